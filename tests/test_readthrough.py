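"""Readthrough efficiency: formula, filters, comparisons, correlations."""

import numpy as np
import pandas as pd
import pytest

from ribostop import annotation, psite, readthrough, stats as rstats, synthetic
from ribostop.readthrough import (
    compare_strain_distributions,
    detectability,
    pool_libraries,
    readthrough_table,
    rpkm,
    rt_length_correlation,
)


class TestRpkm:
    def test_direct_arithmetic(self):
        assert rpkm(10, 500, 1_000_000) == pytest.approx(20.0)

    def test_zero_count(self):
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_zero_length_or_library_hard_error(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = int(rng.integers(0, 1000))
            l = int(rng.integers(1, 5000))
            n = int(rng.integers(1, 10_000_000))
            assert rpkm(c, l, n) == pytest.approx(c / (l / 1e3) / (n / 1e6))


class TestDetectability:
    def test_passing_both_filters(self):
        assert detectability(0.5, 0.15)

    def test_boundaries_are_strict(self):
        assert not detectability(0.2, 0.15)
        assert not detectability(0.5, 0.1)

    def test_zero_extension(self):
        assert not detectability(0.5, 0.0)


def _single_transcript_setup(ext_codons=4, cds_codons=96):
    """One transcript with controlled counts injected directly as P-sites."""
    tr = annotation.Transcript(
        id="t1",
        sequence="G" * 20 + "ATG" + "GCT" * (cds_codons - 1) + "TAA"
        + "GCA" * (ext_codons - 1) + "TGA" + "G" * 60,
        cds_start=20,
        cds_end=20 + 3 * cds_codons,
    )
    part = annotation.partition_regions(tr)
    assert part.rt_extension_length == 3 * ext_codons
    return tr, part


class TestReadthroughTable:
    def test_forced_formula_example(self):
        # ext_frame0=4 over 12 nt vs cds_frame0=285 over 285 nt -> 1/3
        tr, part = _single_transcript_setup(ext_codons=4, cds_codons=100)
        cds_lo = part.cds_start + 15
        rows = []
        # 285 frame-0 CDS P-sites spread over the effective region [cds_lo, cds_end)
        for k in range(285):
            pos = cds_lo + 3 * (k % 95)
            rows.append(("t1", pos, 0, 1, "lib"))
        for k in range(4):
            rows.append(("t1", part.rt_extension[0] + 3 * k, 0, 1, "lib"))
        ps = pd.DataFrame(rows, columns=["transcript_id", "psite_pos", "frame", "count", "library_id"])
        out = readthrough_table(ps, {"t1": part})
        row = out.iloc[0]
        assert row["cds_frame0_count"] == 285
        assert row["cds_effective_length"] == 285
        assert row["ext_frame0_count"] == 4
        assert row["ext_length"] == 12
        assert row["readthrough_efficiency"] == pytest.approx((4 / 12) / (285 / 285))

    def test_zero_extension_reads_give_zero_efficiency_when_detectable(self):
        tr, part = _single_transcript_setup()
        rows = [("t1", part.cds_start + 15 + 3 * k, 0, 5, "lib") for k in range(90)]
        # extension reads in frames 1/2 only: detectable but frame-0 numerator 0
        rows += [("t1", part.rt_extension[0] + 1, 1, 3, "lib")]
        ps = pd.DataFrame(rows, columns=["transcript_id", "psite_pos", "frame", "count", "library_id"])
        out = readthrough_table(ps, {"t1": part})
        row = out.iloc[0]
        assert row["detectable"]
        assert row["readthrough_efficiency"] == 0.0

    def test_head_trim_excludes_first_15nt(self):
        tr, part = _single_transcript_setup()
        rows = [("t1", part.cds_start + 14, 0, 100, "lib"),
                ("t1", part.cds_start + 15, 0, 7, "lib")]
        ps = pd.DataFrame(rows, columns=["transcript_id", "psite_pos", "frame", "count", "library_id"])
        out = readthrough_table(ps, {"t1": part})
        assert out.iloc[0]["cds_frame0_count"] == 7

    def test_open_extension_excluded_by_default(self):
        tr = annotation.Transcript(
            id="t1", sequence="G" * 20 + "ATG" + "GCT" * 29 + "TAA" + "A" * 31,
            cds_start=20, cds_end=110,
        )
        part = annotation.partition_regions(tr)
        assert part.open_extension
        ps = pd.DataFrame(
            [("t1", 50, 0, 5, "lib")],
            columns=["transcript_id", "psite_pos", "frame", "count", "library_id"],
        )
        assert readthrough_table(ps, {"t1": part}).empty
        assert not readthrough_table(ps, {"t1": part}, exclude_open_extension=False).empty

    @staticmethod
    def _raw_ratio(table: pd.DataFrame) -> pd.Series:
        """Efficiency recomputed from the counts, ignoring detectability."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (table["ext_frame0_count"] / table["ext_length"]) / (
                table["cds_frame0_count"] / table["cds_effective_length"]
            )
        return r

    def test_efficiency_invariant_under_downsampling(
        self, std_psites, std_partitions, std_strain_of
    ):
        """Uniform thinning preserves the density ratio in expectation: the
        per-transcript median over 50 half-depth replicates stays within 15%
        of the full-depth value (transcripts with solid extension coverage,
        where the ratio is not dominated by Poisson discreteness)."""
        pooled = pool_libraries(std_psites, std_strain_of)
        sub_full = pooled[pooled["strain"] == "mut2"]
        full = readthrough_table(sub_full, std_partitions, groupby="strain")
        full = full.set_index("transcript_id")
        solid = full.index[full["ext_frame0_count"] >= 8]
        assert len(solid) >= 20
        full_ratio = self._raw_ratio(full.loc[solid])

        rng = np.random.default_rng(1)
        reps = []
        for _ in range(50):
            thin = sub_full.copy()
            thin["count"] = rng.binomial(thin["count"].to_numpy(), 0.5)
            thin = thin[thin["count"] > 0]
            down = readthrough_table(thin, std_partitions, groupby="strain")
            down = down.set_index("transcript_id")
            reps.append(self._raw_ratio(down.reindex(solid)))
        med = pd.concat(reps, axis=1).median(axis=1)
        rel = ((med - full_ratio) / full_ratio).abs()
        assert np.median(rel) < 0.15

    def test_detectable_set_shrinks_when_thresholds_rise(
        self, std_psites, std_partitions, std_strain_of
    ):
        """Filter monotonicity: raising RPKM thresholds never adds mRNAs."""
        pooled = pool_libraries(std_psites, std_strain_of)
        rt = readthrough_table(pooled, std_partitions, groupby="strain")
        base = (rt["cds_rpkm"] > 0.2) & (rt["ext_rpkm"] > 0.1)
        for cds_min, ext_min in [(0.5, 0.1), (0.2, 0.3), (1.0, 1.0)]:
            stricter = (rt["cds_rpkm"] > cds_min) & (rt["ext_rpkm"] > ext_min)
            assert not (stricter & ~base).any()


class TestStrainComparisons:
    def test_identical_distributions_not_rejected(self):
        eff = np.linspace(0.01, 0.2, 40)
        rt = pd.DataFrame(
            {"strain": ["a"] * 40 + ["b"] * 40,
             "readthrough_efficiency": np.concatenate([eff, eff]),
             "detectable": True}
        )
        out = compare_strain_distributions(rt)
        assert (out["padj"] > 0.9).all()

    def test_separated_samples_match_exact_oracle(self):
        rt = pd.DataFrame(
            {"strain": ["a"] * 3 + ["b"] * 3,
             "readthrough_efficiency": [1, 2, 3, 101, 102, 103],
             "detectable": True}
        )
        out = compare_strain_distributions(rt)
        assert out["pvalue"].iloc[0] == pytest.approx(0.1)

    def test_small_strain_skipped_with_warning(self):
        rt = pd.DataFrame(
            {"strain": ["a"] * 10 + ["b"] * 2,
             "readthrough_efficiency": list(range(10)) + [1, 2],
             "detectable": True}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_strain_distributions(rt)
        assert out.empty

    def test_elevated_strain_detected_on_synthetic_data(
        self, std_psites, std_partitions, std_strain_of
    ):
        pooled = pool_libraries(std_psites, std_strain_of)
        rt = readthrough_table(pooled, std_partitions, groupby="strain")
        out = compare_strain_distributions(rt)
        wt_mut2 = out[
            ((out["strain_a"] == "mut2") & (out["strain_b"] == "wt"))
            | ((out["strain_a"] == "wt") & (out["strain_b"] == "mut2"))
        ].iloc[0]
        assert wt_mut2["padj"] < 0.05
        med = {wt_mut2["strain_a"]: wt_mut2["median_a"], wt_mut2["strain_b"]: wt_mut2["median_b"]}
        assert med["mut2"] > med["wt"]
        wt_mut1 = out[
            ((out["strain_a"] == "mut1") & (out["strain_b"] == "wt"))
            | ((out["strain_a"] == "wt") & (out["strain_b"] == "mut1"))
        ].iloc[0]
        assert wt_mut1["padj"] > 0.05


class TestLengthCorrelation:
    def _rt_for(self, transcripts, eff):
        return pd.DataFrame(
            {"transcript_id": list(transcripts), "readthrough_efficiency": eff,
             "detectable": True}
        )

    def test_monotone_decreasing_gives_minus_one(self):
        cfg = synthetic.SimConfig(n_transcripts=30, seed=2)
        trs, _ = synthetic.simulate_transcriptome(cfg)
        lens = np.array([t.utr3_len for t in trs.values()], dtype=float)
        rt = self._rt_for(trs, 1.0 / (1.0 + lens))
        out = rt_length_correlation(rt, trs).set_index("stratum")
        assert out.loc["all", "rho"] == pytest.approx(-1.0)

    def test_independent_pairs_give_small_rho(self):
        rng = np.random.default_rng(3)
        cfg = synthetic.SimConfig(n_transcripts=500, seed=4)
        trs, _ = synthetic.simulate_transcriptome(cfg)
        rt = self._rt_for(trs, rng.uniform(size=len(trs)))
        out = rt_length_correlation(rt, trs, stratify_by_stop=False).set_index("stratum")
        assert abs(out.loc["all", "rho"]) < 0.1

    def test_effect_confined_to_one_stratum(self):
        rng = np.random.default_rng(5)
        cfg = synthetic.SimConfig(n_transcripts=400, seed=6)
        trs, _ = synthetic.simulate_transcriptome(cfg)
        eff = rng.uniform(0.4, 0.6, size=len(trs))
        for i, tr in enumerate(trs.values()):
            if tr.stop_codon == "TGA":
                eff[i] = 1.0 / (1.0 + tr.utr3_len) + rng.normal(0, 1e-4)
        rt = self._rt_for(trs, eff)
        out = rt_length_correlation(rt, trs).set_index("stratum")
        assert out.loc["TGA", "rho"] < -0.9
        assert abs(out.loc["TAA", "rho"]) < 0.2
        assert out.loc["all", "n"] == len(trs)


class TestFrameRestrictedCounting:
    def test_frame0_estimator_less_biased_than_all_frame(self):
        """With imperfect frame fidelity, restricting counts to frame 0 gives
        a less biased readthrough estimate than counting all frames.

        Deep single-strain coverage so detectability selection is negligible
        and the comparison isolates frame contamination."""
        cfg = synthetic.SimConfig(
            n_transcripts=80, seed=21, frame_fidelity=0.9,
            rho_log10_mean=-1.2, rho_log10_sd=0.2,
            ribo_reads_per_transcript=3000,
            strains=(synthetic.StrainConfig("wt"),), replicates=1,
        )
        trs, truth = synthetic.simulate_transcriptome(cfg)
        parts = {tid: annotation.partition_regions(tr) for tid, tr in trs.items()}
        fp = psite.filter_read_lengths(synthetic.simulate_footprints(trs, truth, cfg))
        ps = psite.assign_psites(
            fp, psite.PsiteOffsetTable(dict(cfg.offsets)), trs, parts
        )
        rt = readthrough_table(ps, parts).set_index("transcript_id")
        assert rt["detectable"].mean() > 0.9  # selection negligible

        all_frame = ps.copy()
        all_frame["frame"] = 0  # treat every footprint as in-frame
        rt_all = readthrough_table(all_frame, parts).set_index("transcript_id")

        shared = rt.index[rt["detectable"]].intersection(
            rt_all.index[rt_all["detectable"]]
        )
        rho = truth.loc[shared, "rho_wt"]
        bias_f0 = np.median(rt.loc[shared, "readthrough_efficiency"] - rho)
        bias_all = np.median(rt_all.loc[shared, "readthrough_efficiency"] - rho)
        assert abs(bias_f0) <= abs(bias_all)
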