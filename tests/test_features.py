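"""Sequence feature scanners, tAI weights, stop context, OOF QC."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest

from ribostop import annotation, features, synthetic
from ribostop.features import (
    CodonWeights,
    build_feature_table,
    codon_optimality_score,
    compute_tai,
    context_usage_logratio,
    find_uorfs,
    has_oof_stop_in_cds,
    load_tgcn,
    load_wobble_penalties,
    out_of_frame_qc,
    polyA_region_for_utr5,
    scan_oligoU,
    scan_polyA,
    stop_context_features,
)

from test_annotation import make_transcript

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(seq: str, cds_start: int):
    """Oracle: for every ATG in the 5'-UTR, translate codon by codon."""
    out = []
    for i in range(cds_start - 2):
        if seq[i : i + 3] != "ATG":
            continue
        kind = "overlapping"
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                kind = "upstream" if j + 3 <= cds_start else "overlapping"
                break
        out.append((i, kind))
    return out


class TestUorfs:
    def test_hand_translated_upstream(self):
        # 5'-UTR AAATGGCT TAA ...: ATG at 2, in-frame TAA at 8
        tr = make_transcript("AAATGGCTTAACC", "ATGGCTGCT", "TAAGGGTGAG")
        uorfs = find_uorfs(tr)
        assert len(uorfs) == 1
        assert uorfs[0].start == 2 and uorfs[0].kind == "upstream"

    def test_overlapping_near_boundary(self):
        tr = make_transcript("CCCCATG C".replace(" ", ""), "ATGGCTGCT", "TAAGGGTGAG")
        uorfs = find_uorfs(tr)
        assert [u.kind for u in uorfs] == ["overlapping"]

    def test_no_aug_no_uorf(self):
        tr = make_transcript("CCCCCCCC", "ATGGCTGCT", "TAAGGGTGAG")
        assert find_uorfs(tr) == []

    def test_agrees_with_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 50))))
            tr = make_transcript(utr5, "ATGGCTGCT", "TAAGGGTGAG")
            got = [(u.start, u.kind) for u in find_uorfs(tr)]
            assert got == brute_force_uorfs(tr.sequence, tr.cds_start)


def polyA_oracle(seq: str, window=10, max_other=2) -> bool:
    return any(
        seq[i : i + window].count("A") >= window - max_other
        for i in range(len(seq) - window + 1)
    )


class TestTractScanners:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAAAAA", True),
            ("AAAAGAAAAA", True),   # 1 non-A in the window
            ("AAAAGGAAAA", True),   # 2 non-A
            ("AAAAGGGAAA", False),  # 3 non-A
            ("CCCCCCCCCC", False),
            ("AAAAAAAAA", False),   # 9 nt only
        ],
    )
    def test_polyA_rule(self, seq, expected):
        assert scan_polyA(seq) is expected

    @pytest.mark.parametrize(
        "seq,expected",
        [("TTTTTTT", True), ("TTTTTT", False), ("TTTATTTT", False), ("UUUUUUU", True)],
    )
    def test_oligoU_rule(self, seq, expected):
        assert scan_oligoU(seq) is expected

    def test_polyA_window_may_include_main_aug_A(self):
        # GG + 7 A at the UTR end: only 7 A in any UTR window, but the A of
        # the main AUG completes an 8-A window
        tr = make_transcript("C" * 4 + "GG" + "A" * 7, "ATGGCTGCT", "TAAGGGTGAG")
        assert not scan_polyA(tr.sequence[: tr.cds_start])
        assert scan_polyA(polyA_region_for_utr5(tr))

    def test_scanners_agree_with_oracles_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.2, 0.2, 0.2],
                                     size=int(rng.integers(5, 60))))
            assert scan_polyA(seq) == polyA_oracle(seq)
            assert scan_oligoU(seq) == (re.search("T{7}", seq) is not None)


class TestTai:
    def test_uniform_copies_no_penalty_gives_all_ones(self):
        # every anticodon present with equal copies and s = 0 everywhere
        comp = str.maketrans("ACGT", "TGCA")
        gcn = {"".join(ac): 5.0 for ac in itertools.product("ACGT", repeat=3)}
        s = {"WC": 0.0, "G:U": 0.0, "I:C": 0.0, "I:A": 0.0, "U:G": 0.0}
        w = compute_tai(gcn, s)
        vals = set(w.as_dict().values())
        assert vals == {1.0}

    def test_scale_invariance(self):
        gcn = load_tgcn()
        w1 = compute_tai(gcn)
        w2 = compute_tai({k: 2 * v for k, v in gcn.items()})
        for codon, v in w1.as_dict().items():
            assert w2[codon] == pytest.approx(v)

    def test_zero_weight_replaced_by_geometric_mean(self):
        # single tRNA: decodes GCT (Watson-Crick), GCC (I:C wobble) and GCA
        # (I:A wobble, near-zero); every other codon gets the geometric mean
        # of those nonzero weights
        gcn = {"AGC": 4.0}
        w = compute_tai(gcn)
        d = w.as_dict()
        assert d["GCT"] == 1.0
        assert d["GCC"] == pytest.approx(1 - 0.28)
        assert d["GCA"] == pytest.approx(1 - 0.9999)
        decoded = {"GCT", "GCC", "GCA"}
        others = [v for c, v in d.items() if c not in decoded]
        gm = np.exp(np.mean(np.log([d[c] for c in decoded])))
        assert np.allclose(others, gm)

    def test_all_zero_copies_hard_error(self):
        with pytest.raises(ValueError):
            compute_tai({"AGC": 0.0})

    def test_bundled_tables_satisfy_invariants(self):
        s = load_wobble_penalties()
        assert s["WC"] == 0.0 and all(0 <= v <= 1 for v in s.values())
        w = compute_tai(load_tgcn(), s)
        vals = list(w.as_dict().values())
        assert max(vals) == 1.0 and min(vals) > 0
        assert all(c not in w for c in STOPS)


class TestCodonOptimality:
    def _weights(self, mapping):
        all_codons = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
        full = {c: 0.5 for c in all_codons if c not in STOPS}
        full.update(mapping)
        mx = max(full.values())
        return CodonWeights({c: v / mx for c, v in full.items()})

    def test_repeated_codon_identity(self):
        w = self._weights({"GCT": 1.0, "GGG": 0.5})
        assert codon_optimality_score("GGGGGGGGG", w) == pytest.approx(0.5)

    def test_two_codon_geometric_mean(self):
        w = self._weights({"GCT": 1.0, "AAA": 0.25})
        assert codon_optimality_score("AAAGCT", w) == pytest.approx(0.5)

    def test_matches_log_mean_oracle_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        w = compute_tai(load_tgcn())
        sense = synthetic.SENSE_CODONS
        for _ in range(200):
            codons = [sense[i] for i in rng.integers(len(sense), size=int(rng.integers(2, 50)))]
            cds = "".join(codons)
            expected = np.exp(np.mean([np.log(w[c]) for c in codons]))
            got = codon_optimality_score(cds, w)
            assert got == pytest.approx(expected, rel=1e-12)
            rng.shuffle(codons)
            assert codon_optimality_score("".join(codons), w) == pytest.approx(got, rel=1e-12)
            assert min(w[c] for c in codons) <= got <= max(w[c] for c in codons)


class TestStopContext:
    def test_direct_read_off(self):
        tr = make_transcript("G" * 6, "ATGGGTGCT", "TAAGCGTACGT")
        ctx = stop_context_features(tr)
        assert ctx["stop_codon"] == "TAA"
        assert ctx["p_site_codon"] == "GCT"
        assert ctx["nt_plus4"] == "G"
        assert ctx["nt_plus5"] == "C"
        assert not ctx["context_truncated"]

    def test_short_utr3_truncation(self):
        # 2 nt after the stop: +4 and +5 present, +6 absent
        tr = make_transcript("G" * 6, "ATGGCT", "TAAGC")
        ctx = stop_context_features(tr)
        assert ctx["nt_plus4"] == "G" and ctx["nt_plus5"] == "C"
        assert ctx["nt_plus6"] is None and ctx["context_truncated"]

    def test_fixture_against_hand_annotation(self):
        cfg = synthetic.SimConfig(n_transcripts=20, seed=8)
        trs, truth = synthetic.simulate_transcriptome(cfg)
        for tid, tr in trs.items():
            ctx = stop_context_features(tr)
            assert ctx["stop_codon"] == truth.loc[tid, "stop_codon"]
            assert ctx["p_site_codon"] == tr.sequence[tr.cds_end - 3 : tr.cds_end]
            assert ctx["nt_plus4"] == tr.sequence[tr.cds_end + 3]


class TestContextUsage:
    def test_identical_group_zero_logratio(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=18)) for _ in range(100)]
        tidy, tests = context_usage_logratio({"Reference": seqs, "Up": list(seqs)})
        up = tidy[(tidy["group"] == "Up") & ~tidy["masked"] & tidy["prop"].gt(0)]
        assert np.allclose(up["log2_ratio"].dropna(), 0.0)
        assert (tests["padj"] > 0.99).all()

    def test_forced_nucleotide_detected(self):
        rng = np.random.default_rng(4)
        ref = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(200)]
        up = ["A" + s[1:] for s in ("".join(rng.choice(list("ACGT"), size=10))
                                    for _ in range(200))]
        tidy, tests = context_usage_logratio({"Reference": ref, "Up": up})
        row = tidy[(tidy["group"] == "Up") & (tidy["position"] == 0) & (tidy["nt"] == "A")]
        assert row["log2_ratio"].iloc[0] > 0.5
        pos0 = tests[tests["comparison"].str.endswith("@ 0")]
        assert (pos0["padj"] < 0.01).any()

    def test_proportions_sum_to_one_per_position(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(50)]
        tidy, _ = context_usage_logratio({"Reference": seqs, "G": seqs[:25]})
        sums = tidy.groupby(["group", "position"])["prop"].sum()
        assert np.allclose(sums, 1.0)


def oof_stop_oracle(seq, cds_start, cds_end):
    return any(
        seq[j : j + 3] in STOPS
        for shift in (1, 2)
        for j in range(cds_start + shift, cds_end - 2, 3)
    )


class TestOutOfFrameQc:
    def test_planted_plus_one_frame_stop(self):
        # CDS codons ATG GTA AGG are all sense; the +1-frame triplet at
        # offset 4 reads TAA
        tr = make_transcript("GGG", "ATGGTAAGG", "TAAGGGTGAG")
        assert has_oof_stop_in_cds(tr)
        # and a CDS free of shifted stops stays False
        tr2 = make_transcript("GGG", "ATG" + "GGC" * 5, "TAAGGGTGAG")
        assert not has_oof_stop_in_cds(tr2)

    def test_scanner_agrees_with_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            from conftest import random_transcript

            tr = random_transcript(rng)
            assert has_oof_stop_in_cds(tr) == oof_stop_oracle(
                tr.sequence, tr.cds_start, tr.cds_end
            )

    def test_all_frame0_window_gives_zero_fraction(self):
        tr = make_transcript("G" * 20, "ATG" + "GCT" * 40, "TAAGGGTGAGGGGG")
        parts = {"t1": annotation.partition_regions(tr)}
        ps = pd.DataFrame(
            {"transcript_id": "t1", "psite_pos": [tr.cds_end - 3 * k - 3 for k in range(5)],
             "frame": 0, "count": 20, "library_id": "lib"}
        )
        table, _ = out_of_frame_qc(ps, {"t1": tr}, parts)
        assert table.iloc[0]["oof_fraction"] == 0.0

    def test_fidelity_recovered_in_window(self, std_sim, std_psites, std_partitions, std_config):
        transcripts, _, _ = std_sim
        table, _ = out_of_frame_qc(std_psites, transcripts, std_partitions)
        ok = table[table["window_reads"] >= 30]
        n = ok["window_reads"].sum()
        p = 1 - std_config.frame_fidelity
        pooled_oof = (ok["oof_fraction"] * ok["window_reads"]).sum() / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(pooled_oof - p) < 3 * se + 0.01  # background adds a little


class TestFeatureTable:
    def test_matches_truth_flags_and_is_deterministic(self, std_sim, std_partitions):
        transcripts, truth, _ = std_sim
        t1 = build_feature_table(transcripts, std_partitions)
        t2 = build_feature_table(transcripts, std_partitions)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["polyA_5utr"] == truth["polyA_5utr"]).all()
        assert (t1["oligoU_3utr"] == truth["oligoU_3utr"]).all()
        assert (t1["stop_codon"] == truth["stop_codon"]).all()
        assert (t1["ext_length"] == truth["ext_length"]).all()
        assert ((t1["codon_optimality"] > 0) & (t1["codon_optimality"] <= 1)).all()
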