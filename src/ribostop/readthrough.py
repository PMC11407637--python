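"""Per-mRNA stop-codon readthrough efficiency.

Readthrough efficiency compares in-frame ribosome density downstream of the
canonical stop with in-frame density over the CDS::

    RE = (frame-0 count in extension / extension length)
         / (frame-0 count in CDS / CDS length)

where the extension runs from the canonical stop codon (inclusive) to the
next in-frame stop codon (exclusive) and the first 15 nt of the CDS are
excluded from both the count and the length, avoiding the initiation peak.
An mRNA is "detectable" — and its efficiency reported — only when the CDS
RPKM exceeds 0.2 and the extension RPKM exceeds 0.1 (strict inequalities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ribostop import stats as rstats
from ribostop.annotation import RegionPartition, Transcript

logger = logging.getLogger(__name__)

CDS_RPKM_MIN = 0.2
EXT_RPKM_MIN = 0.1
#: nt trimmed from the CDS 5' end (initiation-ramp exclusion)
CDS_HEAD_TRIM = 15


def rpkm(count: float, length: int, library_size: int) -> float:
    """Reads per kilobase of region per million library reads."""
    if length <= 0:
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (length / 1e3) / (library_size / 1e6)


def readthrough_table(
    psites: pd.DataFrame,
    partitions: Mapping[str, RegionPartition],
    library_sizes: Mapping[str, int] | None = None,
    groupby: str = "library_id",
    exclude_open_extension: bool = True,
) -> pd.DataFrame:
    """Per-transcript, per-group readthrough efficiencies.

    ``groupby`` is typically ``library_id``; to pool replicates, map
    ``library_id`` to a strain column first (see :func:`pool_libraries`).
    Library size defaults to the total P-site count of the group — the most
    self-contained definition — but can be supplied explicitly.

    Returns one row per transcript x group with counts, RPKMs, efficiency
    (NaN when not detectable) and the ``detectable`` flag. Transcripts whose
    extension has no terminating in-frame stop are excluded by default.
    """
    df = psites[psites["transcript_id"].isin(partitions.keys())]
    groups = sorted(df[groupby].unique())
    if library_sizes is None:
        library_sizes = df.groupby(groupby)["count"].sum().to_dict()

    geom = []
    for tid, part in partitions.items():
        if exclude_open_extension and part.open_extension:
            continue
        cds_lo = part.cds_start + CDS_HEAD_TRIM
        cds_len_eff = part.cds_end - cds_lo
        ext_lo, ext_hi = part.rt_extension
        if cds_len_eff <= 0 or ext_hi - ext_lo <= 0:
            continue
        geom.append((tid, cds_lo, part.cds_end, ext_lo, ext_hi))
    if not geom:
        return pd.DataFrame()
    gdf = pd.DataFrame(
        geom, columns=["transcript_id", "cds_lo", "cds_end", "ext_lo", "ext_hi"]
    ).set_index("transcript_id")

    df = df[df["transcript_id"].isin(gdf.index)]
    pos = df["psite_pos"].to_numpy()
    cnt = df["count"].to_numpy(dtype=float)
    f0 = (df["frame"].to_numpy() == 0)
    cds_lo = gdf["cds_lo"].reindex(df["transcript_id"]).to_numpy()
    ce = gdf["cds_end"].reindex(df["transcript_id"]).to_numpy()
    ext_lo = gdf["ext_lo"].reindex(df["transcript_id"]).to_numpy()
    ext_hi = gdf["ext_hi"].reindex(df["transcript_id"]).to_numpy()
    in_cds = (pos >= cds_lo) & (pos < ce)
    in_ext = (pos >= ext_lo) & (pos < ext_hi)

    agg = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"].to_numpy(),
            groupby: df[groupby].to_numpy(),
            "cds_all": cnt * in_cds,
            "cds_f0": cnt * (in_cds & f0),
            "ext_all": cnt * in_ext,
            "ext_f0": cnt * (in_ext & f0),
        }
    ).groupby(["transcript_id", groupby]).sum()
    full = pd.MultiIndex.from_product([gdf.index, groups], names=["transcript_id", groupby])
    agg = agg.reindex(full, fill_value=0.0).reset_index()

    cds_len_eff = (gdf["cds_end"] - gdf["cds_lo"]).reindex(agg["transcript_id"]).to_numpy()
    ext_len = (gdf["ext_hi"] - gdf["ext_lo"]).reindex(agg["transcript_id"]).to_numpy()
    lib = agg[groupby].map(library_sizes).fillna(0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cds_rpkm_v = np.where(lib > 0, agg["cds_all"] / (cds_len_eff / 1e3) / (lib / 1e6), 0.0)
        ext_rpkm_v = np.where(lib > 0, agg["ext_all"] / (ext_len / 1e3) / (lib / 1e6), 0.0)
        det = (cds_rpkm_v > CDS_RPKM_MIN) & (ext_rpkm_v > EXT_RPKM_MIN)
        eff = np.where(
            det & (agg["cds_f0"] > 0),
            (agg["ext_f0"] / ext_len) / np.where(agg["cds_f0"] > 0, agg["cds_f0"], 1.0)
            * cds_len_eff,
            np.nan,
        )
    n_zero_f0 = int((det & (agg["cds_f0"] == 0)).sum())
    if n_zero_f0:
        logger.info("%d transcript/group pairs pass filters with zero frame-0 CDS count", n_zero_f0)

    return pd.DataFrame(
        {
            "transcript_id": agg["transcript_id"],
            groupby: agg[groupby],
            "cds_frame0_count": agg["cds_f0"],
            "cds_effective_length": cds_len_eff,
            "ext_frame0_count": agg["ext_f0"],
            "ext_length": ext_len,
            "cds_rpkm": cds_rpkm_v,
            "ext_rpkm": ext_rpkm_v,
            "readthrough_efficiency": eff,
            "detectable": det,
        }
    )


def detectability(cds_rpkm: float, ext_rpkm: float) -> bool:
    """Readthrough is detectable when CDS RPKM > 0.2 and extension RPKM > 0.1."""
    return (cds_rpkm > CDS_RPKM_MIN) and (ext_rpkm > EXT_RPKM_MIN)


def pool_libraries(psites: pd.DataFrame, strain_of: Mapping[str, str]) -> pd.DataFrame:
    """Pool replicate libraries into strains: adds a ``strain`` column from a
    library_id -> strain mapping."""
    out = psites.copy()
    out["strain"] = out["library_id"].map(strain_of)
    if out["strain"].isna().any():
        missing = sorted(out.loc[out["strain"].isna(), "library_id"].unique())
        raise KeyError(f"libraries with no strain assignment: {missing}")
    return out


def compare_strain_distributions(
    rt: pd.DataFrame, group_col: str = "strain", min_n: int = 3
) -> pd.DataFrame:
    """All pairwise rank-sum comparisons of detectable readthrough
    efficiencies between strains, BH-adjusted across the pairs.

    Strains with fewer than ``min_n`` detectable mRNAs are skipped with a
    warning. Returns a frame with one row per pair.
    """
    det = rt[rt["detectable"] & rt["readthrough_efficiency"].notna()]
    by_strain = {s: g["readthrough_efficiency"].to_numpy() for s, g in det.groupby(group_col)}
    usable = {}
    for s, v in by_strain.items():
        if v.size < min_n:
            warnings.warn(f"strain {s}: only {v.size} detectable mRNAs; comparison skipped")
        else:
            usable[s] = v
    strains = sorted(usable)
    results = []
    labels = []
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            res = rstats.rank_sum_test(usable[a], usable[b])
            res.comparison = f"{a} vs {b}"
            results.append(res)
            labels.append((a, b))
    rstats.attach_bh(results)
    return pd.DataFrame(
        {
            "strain_a": [a for a, _ in labels],
            "strain_b": [b for _, b in labels],
            "n_a": [r.n[0] for r in results],
            "n_b": [r.n[1] for r in results],
            "statistic": [r.statistic for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
            "median_a": [float(np.median(usable[a])) for a, _ in labels],
            "median_b": [float(np.median(usable[b])) for _, b in labels],
        }
    )


def rt_length_correlation(
    rt: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    stratify_by_stop: bool = True,
    low_n: int = 10,
) -> pd.DataFrame:
    """Spearman correlation between readthrough efficiency and 3'-UTR length,
    for all detectable mRNAs ("all") and stratified by stop codon.

    Apply the gene-overlap filter to ``rt`` beforehand when emulating the
    minimally-overlapping-genes analysis. Strata with fewer than ``low_n``
    mRNAs are reported with a ``low_n`` flag rather than dropped.
    """
    det = rt[rt["detectable"] & rt["readthrough_efficiency"].notna()].copy()
    det["utr3_len"] = det["transcript_id"].map(
        lambda t: transcripts[t].utr3_len if t in transcripts else np.nan
    )
    det["stop_codon"] = det["transcript_id"].map(
        lambda t: transcripts[t].stop_codon if t in transcripts else None
    )
    det = det.dropna(subset=["utr3_len"])

    strata: list[tuple[str, pd.DataFrame]] = [("all", det)]
    if stratify_by_stop:
        strata += [(sc, det[det["stop_codon"] == sc]) for sc in ("TAA", "TAG", "TGA")]

    rows = []
    for name, sub in strata:
        n = len(sub)
        if n < 3:
            rows.append({"stratum": name, "rho": np.nan, "pvalue": np.nan, "n": n,
                         "low_n": True})
            continue
        res = rstats.spearman(sub["readthrough_efficiency"], sub["utr3_len"])
        rows.append({"stratum": name, "rho": res.statistic, "pvalue": res.pvalue,
                     "n": n, "low_n": n < low_n})
    return pd.DataFrame(rows)
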