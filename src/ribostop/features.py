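"""Per-mRNA sequence features used in readthrough analysis.

Covers upstream open reading frames (uORFs), poly(A) and oligo(U) tracts in
the UTRs, tAI-based codon optimality, the nucleotide context around the stop
codon, nucleotide-usage log-ratios between gene groups, and out-of-frame
footprint QC.

Conventions: sequences are handled in the DNA alphabet (U -> T); "A/U"
below always means A/T internally. The stop codon occupies context positions
+1+2+3, the first 3'-UTR nucleotide after it is +4.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ribostop import stats as rstats
from ribostop.annotation import STOP_CODONS, RegionPartition, Transcript

NUCLEOTIDES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# uORFs

@dataclass(frozen=True)
class Uorf:
    start: int  # transcript offset of the A of the uORF AUG
    stop_end: int | None  # exclusive end of the uORF stop codon; None if none found
    kind: str  # "upstream" | "overlapping"


def find_uorfs(transcript: Transcript) -> list[Uorf]:
    """All AUG-initiated upstream ORFs in the 5'-UTR, no minimum length.

    An AUG starting anywhere in the 5'-UTR opens a uORF. Reading in that
    frame, if the first stop codon ends at or before ``cds_start`` the uORF
    is *upstream*; if translation would continue past the main start codon
    (including when no stop exists before the transcript end) it is
    *overlapping*.
    """
    seq = transcript.sequence
    cs = transcript.cds_start
    out: list[Uorf] = []
    for m in re.finditer("ATG", seq[:cs]):
        i = m.start()
        stop_end = None
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                stop_end = j + 3
                break
        if stop_end is not None and stop_end <= cs:
            out.append(Uorf(i, stop_end, "upstream"))
        else:
            out.append(Uorf(i, stop_end, "overlapping"))
    return out


# ---------------------------------------------------------------------------
# tract scanners

def scan_polyA(region_seq: str, window: int = 10, max_other: int = 2) -> bool:
    """Poly(A) tract: some ``window``-nt stretch with at most ``max_other``
    non-A nucleotides (i.e. >= 8 A in a 10-nt window by default).

    For 5'-UTR scanning, pass the UTR plus the A of the main AUG so a tract
    running into the start codon is counted (see
    :func:`polyA_region_for_utr5`).
    """
    s = region_seq.upper().replace("U", "T")
    if len(s) < window:
        return False
    is_a = np.frombuffer(s.encode(), dtype=np.uint8) == ord("A")
    run = np.convolve(is_a.astype(int), np.ones(window, dtype=int), mode="valid")
    return bool((run >= window - max_other).any())


def polyA_region_for_utr5(transcript: Transcript) -> str:
    """The 5'-UTR extended through the A of the main AUG, for poly(A) scans."""
    return transcript.sequence[: transcript.cds_start + 1]


def scan_oligoU(region_seq: str, min_len: int = 7) -> bool:
    """Oligo(U) tract: an uninterrupted run of at least ``min_len`` U."""
    s = region_seq.upper().replace("U", "T")
    return re.search("T" * min_len, s) is not None


# ---------------------------------------------------------------------------
# tAI codon optimality

#: wobble pairing rules: codon third base -> [(anticodon wobble base, pairing class)]
#: the Watson-Crick decoder comes first; anticodon written 5'->3', so its
#: first base pairs the codon's third base.
WOBBLE_RULES: dict[str, list[tuple[str, str]]] = {
    "T": [("A", "WC"), ("G", "G:U")],
    "C": [("G", "WC"), ("A", "I:C")],  # A34 is read as inosine
    "A": [("T", "WC"), ("A", "I:A")],
    "G": [("C", "WC"), ("T", "U:G")],
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class CodonWeights:
    """tAI decoding weights per sense codon.

    ``W_i = sum_j (1 - s_ij) * tGCN_j`` over the anticodons that decode codon
    i (Watson-Crick plus one wobble decoder per the standard rules);
    ``w_i = W_i / max(W)``, with zero weights replaced by the geometric mean
    of the nonzero weights so every codon scores > 0.
    """

    def __init__(self, weights: Mapping[str, float]):
        w = {k: float(v) for k, v in weights.items()}
        if not w or not np.isclose(max(w.values()), 1.0):
            raise ValueError("weights must be normalized to max 1")
        if any(v <= 0 for v in w.values()):
            raise ValueError("all weights must be positive after zero-replacement")
        self._w = w

    def __getitem__(self, codon: str) -> float:
        return self._w[codon.upper().replace("U", "T")]

    def __contains__(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self._w

    def as_dict(self) -> dict[str, float]:
        return dict(self._w)


def compute_tai(
    gcn: Mapping[str, float], s: Mapping[str, float] | None = None
) -> CodonWeights:
    """tAI codon weights from tRNA gene copy numbers and wobble penalties.

    ``gcn`` maps anticodons (5'->3', DNA alphabet) to gene copy numbers;
    ``s`` maps pairing classes (WC, G:U, I:C, I:A, U:G) to selective
    penalties in [0, 1] (defaults: the standard published vector). Stop
    codons are excluded.
    """
    if s is None:
        s = load_wobble_penalties()
    gcn = {k.upper().replace("U", "T"): float(v) for k, v in gcn.items()}
    if any(v < 0 for v in gcn.values()):
        raise ValueError("copy numbers must be nonnegative")
    if all(v == 0 for v in gcn.values()):
        raise ValueError("all tRNA copy numbers are zero")
    for cls, val in s.items():
        if not 0 <= val <= 1:
            raise ValueError(f"penalty {cls}={val} outside [0, 1]")

    W: dict[str, float] = {}
    for c1 in NUCLEOTIDES:
        for c2 in NUCLEOTIDES:
            for c3 in NUCLEOTIDES:
                codon = c1 + c2 + c3
                if codon in STOP_CODONS:
                    continue
                body = _revcomp(codon[:2])  # anticodon positions 35,36
                total = 0.0
                for wob, cls in WOBBLE_RULES[c3]:
                    total += (1.0 - s[cls]) * gcn.get(wob + body, 0.0)
                W[codon] = total

    wmax = max(W.values())
    if wmax == 0:
        raise ValueError("no codon is decoded by any supplied tRNA")
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = float(np.exp(np.mean(np.log(nonzero))))
    w = {c: (v if v > 0 else gm) for c, v in w.items()}
    return CodonWeights(w)


def codon_optimality_score(cds_seq: str, weights: CodonWeights) -> float:
    """Geometric mean of tAI weights over all CDS codons (stop excluded)."""
    s = cds_seq.upper().replace("U", "T")
    if len(s) % 3 != 0 or not s:
        raise ValueError("CDS length must be a positive multiple of 3")
    logs = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} inside CDS at offset {i}")
        logs.append(np.log(weights[codon]))
    return float(np.exp(np.mean(logs)))


def load_wobble_penalties(path: str | Path | None = None) -> dict[str, float]:
    """The wobble penalty vector (editable TSV: pairing_class, s)."""
    if path is None:
        path = resources.files("ribostop") / "data" / "wobble_penalties.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["pairing_class"], df["s"].astype(float)))


def load_tgcn(path: str | Path | None = None) -> dict[str, float]:
    """tRNA gene copy numbers (TSV: anticodon, copy_number). The bundled
    default is a synthetic yeast-like table for tests and simulations."""
    if path is None:
        path = resources.files("ribostop") / "data" / "tgcn_synthetic_yeastlike.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["anticodon"], df["copy_number"].astype(float)))


# ---------------------------------------------------------------------------
# stop context

def stop_context_features(transcript: Transcript, n_after: int = 6) -> dict:
    """Stop codon identity and its local context.

    Returns the stop codon, the last sense (P-site) codon, and the
    nucleotides at +4..+(3+n_after) (stop codon = +1+2+3; +4 is the first nt
    after it). Positions beyond the transcript end are None and flagged.
    """
    seq = transcript.sequence
    ce = transcript.cds_end
    out: dict = {
        "transcript_id": transcript.id,
        "stop_codon": transcript.stop_codon,
        "p_site_codon": seq[ce - 3 : ce],
        "utr3_len": transcript.utr3_len,
    }
    truncated = False
    for k in range(n_after):
        pos = ce + 3 + k
        key = f"nt_plus{4 + k}"
        if pos < len(seq):
            out[key] = seq[pos]
        else:
            out[key] = None
            truncated = True
    out["context_truncated"] = truncated
    return out


# ---------------------------------------------------------------------------
# nucleotide-usage log-ratios between groups

def context_usage_logratio(
    sequences: Mapping[str, Sequence[str]],
    reference: str = "Reference",
    min_obs: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position nucleotide-usage log-ratios of gene groups vs a reference.

    ``sequences`` maps group name to a list of equal-anchored strings (e.g.
    the 18 nt upstream of the AUG, or the first 18 nt of the 5'-UTR);
    shorter strings contribute only the positions they cover. Returns

    * a tidy frame ``group, position, nt, prop, log2_ratio`` where
      ``log2_ratio = log2(prop_group / prop_reference)`` (positions with
      fewer than ``min_obs`` observations in either group are masked), and
    * chi-squared tests of the position's nucleotide counts for each
      group-vs-reference and all group-vs-group pairs, BH-adjusted.
    """
    if reference not in sequences:
        raise KeyError(f"reference group {reference!r} missing")

    def counts_of(seqs: Sequence[str]) -> pd.DataFrame:
        max_len = max((len(s) for s in seqs), default=0)
        mat = np.zeros((max_len, 4), dtype=int)
        for s in seqs:
            s = s.upper().replace("U", "T")
            for i, ch in enumerate(s):
                if ch in NUCLEOTIDES:
                    mat[i, NUCLEOTIDES.index(ch)] += 1
        return pd.DataFrame(mat, columns=list(NUCLEOTIDES))

    counts = {g: counts_of(seqs) for g, seqs in sequences.items()}
    ref_counts = counts[reference]
    ref_prop = ref_counts.div(ref_counts.sum(axis=1).replace(0, np.nan), axis=0)

    rows = []
    for g, cnt in counts.items():
        prop = cnt.div(cnt.sum(axis=1).replace(0, np.nan), axis=0)
        for pos in cnt.index:
            n_g = cnt.loc[pos].sum()
            n_r = ref_counts.loc[pos].sum() if pos in ref_counts.index else 0
            masked = (n_g < min_obs) or (n_r < min_obs)
            for nt in NUCLEOTIDES:
                pg = prop.loc[pos, nt]
                pr = ref_prop.loc[pos, nt] if pos in ref_prop.index else np.nan
                with np.errstate(divide="ignore", invalid="ignore"):
                    lr = np.nan if masked else float(np.log2(pg / pr)) if pg and pr else np.nan
                rows.append({"group": g, "position": pos, "nt": nt,
                             "prop": pg, "log2_ratio": lr, "masked": masked})
    tidy = pd.DataFrame(rows)

    groups = sorted(sequences)
    tests = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            common = counts[a].index.intersection(counts[b].index)
            for pos in common:
                ta = counts[a].loc[pos].to_numpy()
                tb = counts[b].loc[pos].to_numpy()
                if ta.sum() < min_obs or tb.sum() < min_obs:
                    continue
                keep = (ta + tb) > 0
                tests.append((f"{a} vs {b} @ {pos}", np.vstack([ta[keep], tb[keep]])))
    results = rstats.pairwise_count_tests(dict(tests), method="chi2")
    test_df = pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "statistic": [r.statistic for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
        }
    )
    return tidy, test_df


# ---------------------------------------------------------------------------
# out-of-frame QC

def has_oof_stop_in_cds(transcript: Transcript) -> bool:
    """True when a stop triplet occurs in frame +1 or +2 within the CDS."""
    seq = transcript.sequence
    for shift in (1, 2):
        for j in range(transcript.cds_start + shift, transcript.cds_end - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                return True
    return False


def out_of_frame_qc(
    psites: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    partitions: Mapping[str, RegionPartition],
    library_sizes: Mapping[str, int] | None = None,
    window: int = 30,
    min_window_reads: int = 30,
    cds_rpkm_min: float = 0.2,
    utr3_rpkm_min: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Out-of-frame footprint QC over the last ``window`` nt of the CDS.

    Per gene (pooled over libraries): the fraction of non-frame-0 P-sites in
    the window, total 3'-UTR footprint density (RPKM, stop codon included),
    and the out-of-frame-stop-in-CDS flag. The summary dict carries the
    Spearman correlation between OOF fraction and 3'-UTR RPKM (genes passing
    the RPKM and window-count filters) and a rank-sum comparison of 3'-UTR
    RPKM by OOF-stop flag (RPKM filters only).
    """
    df = psites[psites["transcript_id"].isin(transcripts.keys())]
    if library_sizes is None:
        lib_total = int(df["count"].sum())
    else:
        lib_total = int(sum(library_sizes.values()))

    rows = []
    grouped = dict(tuple(df.groupby("transcript_id")))
    for tid, tr in transcripts.items():
        if not tr.has_utr_annotation or tr.utr3_len <= 0:
            continue
        part = partitions[tid]
        g = grouped.get(tid)
        win_lo = max(part.cds_start, part.cds_end - window)
        if g is None:
            win_tot = win_oof = cds_count = utr3_count = 0.0
        else:
            pos = g["psite_pos"].to_numpy()
            frame = g["frame"].to_numpy()
            cnt = g["count"].to_numpy(dtype=float)
            in_win = (pos >= win_lo) & (pos < part.cds_end)
            win_tot = float(cnt[in_win].sum())
            win_oof = float(cnt[in_win & (frame != 0)].sum())
            cds_count = float(cnt[(pos >= part.cds_start) & (pos < part.cds_end)].sum())
            utr3_count = float(cnt[pos >= part.cds_end].sum())
        cds_rpkm = cds_count / (tr.cds_len / 1e3) / (lib_total / 1e6) if lib_total else 0.0
        utr3_rpkm = (
            utr3_count / (tr.utr3_len / 1e3) / (lib_total / 1e6) if lib_total else 0.0
        )
        rows.append(
            {
                "transcript_id": tid,
                "window_reads": win_tot,
                "oof_fraction": win_oof / win_tot if win_tot > 0 else np.nan,
                "cds_rpkm": cds_rpkm,
                "utr3_rpkm": utr3_rpkm,
                "has_oof_stop_in_cds": has_oof_stop_in_cds(tr),
            }
        )
    table = pd.DataFrame(rows)

    summary: dict = {}
    ok = table[
        (table["cds_rpkm"] > cds_rpkm_min)
        & (table["utr3_rpkm"] > utr3_rpkm_min)
        & (table["window_reads"] >= min_window_reads)
    ]
    if len(ok) >= 3:
        res = rstats.spearman(ok["oof_fraction"], ok["utr3_rpkm"])
        summary["oof_vs_utr3_rho"] = res.statistic
        summary["oof_vs_utr3_p"] = res.pvalue
        summary["oof_vs_utr3_n"] = len(ok)
    flag_ok = table[(table["cds_rpkm"] > cds_rpkm_min) & (table["utr3_rpkm"] > utr3_rpkm_min)]
    yes = flag_ok.loc[flag_ok["has_oof_stop_in_cds"], "utr3_rpkm"]
    no = flag_ok.loc[~flag_ok["has_oof_stop_in_cds"], "utr3_rpkm"]
    if min(len(yes), len(no)) >= 3:
        res = rstats.rank_sum_test(yes, no)
        summary["oofstop_utr3_rpkm_p"] = res.pvalue
        summary["oofstop_n_yes"] = len(yes)
        summary["oofstop_n_no"] = len(no)
    return table, summary


# ---------------------------------------------------------------------------
# feature table assembly

def build_feature_table(
    transcripts: Mapping[str, Transcript],
    partitions: Mapping[str, RegionPartition],
    weights: CodonWeights | None = None,
) -> pd.DataFrame:
    """One row of model-ready features per UTR-annotated transcript.

    Columns: lengths (5'-UTR, CDS, 3'-UTR, transcript, extension), uORF
    flags and count, poly(A)/oligo(U) tract flags per UTR, codon optimality
    (geometric-mean tAI), stop codon, P-site codon, +4..+9 context
    nucleotides, and the out-of-frame-stop flag. Negative-control columns
    are added separately (:func:`ribostop.rf_importance.augment_negative_controls`).
    """
    if weights is None:
        weights = compute_tai(load_tgcn())
    rows = []
    for tid, tr in transcripts.items():
        if not tr.has_utr_annotation:
            continue
        part = partitions[tid]
        uorfs = find_uorfs(tr)
        utr5 = tr.sequence[: tr.cds_start]
        utr3 = tr.sequence[tr.cds_end :]  # stop codon included
        ctx = stop_context_features(tr)
        rows.append(
            {
                "transcript_id": tid,
                "utr5_len": tr.utr5_len,
                "cds_len": tr.cds_len,
                "utr3_len": tr.utr3_len,
                "transcript_len": len(tr.sequence),
                "ext_length": part.rt_extension_length,
                "n_uorfs": len(uorfs),
                "has_uorf": len(uorfs) > 0,
                "has_upstream_uorf": any(u.kind == "upstream" for u in uorfs),
                "has_overlapping_uorf": any(u.kind == "overlapping" for u in uorfs),
                "polyA_5utr": scan_polyA(polyA_region_for_utr5(tr)),
                "polyA_3utr": scan_polyA(utr3),
                "oligoU_5utr": scan_oligoU(utr5),
                "oligoU_3utr": scan_oligoU(utr3),
                "codon_optimality": codon_optimality_score(
                    tr.sequence[tr.cds_start : tr.cds_end], weights
                ),
                "stop_codon": ctx["stop_codon"],
                "p_site_codon": ctx["p_site_codon"],
                "nt_plus4": ctx["nt_plus4"],
                "nt_plus5": ctx["nt_plus5"],
                "nt_plus6": ctx["nt_plus6"],
                "nt_plus7": ctx["nt_plus7"],
                "nt_plus8": ctx["nt_plus8"],
                "nt_plus9": ctx["nt_plus9"],
                "has_oof_stop_in_cds": has_oof_stop_in_cds(tr),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
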