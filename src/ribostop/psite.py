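"""Footprint length filtering, P-site assignment, metagene profiles, and
frame-resolved region accounting.

Footprints are carried as pandas DataFrames with columns
``transcript_id, five_prime_pos, read_length, count, library_id``
(``count`` collapses identical records; ``library_id`` identifies the
sequencing library). A P-site table adds ``psite_pos``, ``frame`` and
``region``.

The reading frame is ``(psite_pos - cds_start) mod 3``: frame 0 is the
annotated CDS frame and, within the readthrough extension, the frame a
readthrough ribosome keeps.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ribostop.annotation import REGION_LABELS, RegionPartition, Transcript

logger = logging.getLogger(__name__)

#: footprint lengths retained by default: 20-23 nt (short, empty-A-site) and
#: 27-32 nt (canonical 80S footprints)
DEFAULT_KEEP_LENGTHS = frozenset(range(20, 24)) | frozenset(range(27, 33))

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "read_length", "count", "library_id"]


def read_footprint_tsv(path: str | Path, library_id: str | None = None) -> pd.DataFrame:
    """Read a footprint TSV (transcript_id, five_prime_pos, read_length[, count])."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if "count" not in df.columns:
        df["count"] = 1
    if "library_id" not in df.columns:
        df["library_id"] = library_id if library_id is not None else Path(path).stem
    return df[FOOTPRINT_COLUMNS]


def read_footprint_bam(path: str | Path, library_id: str | None = None) -> pd.DataFrame:
    """Read transcript-space alignments (reference name = transcript id) into
    the footprint frame. Accepts SAM or BAM; unmapped and reverse-strand
    records are dropped."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_reverse:
                continue
            rows.append((aln.reference_name, aln.reference_start, aln.query_length))
    df = pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "read_length"])
    df = (
        df.groupby(FOOTPRINT_COLUMNS[:3], as_index=False, sort=False)
        .size()
        .rename(columns={"size": "count"})
    )
    df["library_id"] = library_id if library_id is not None else Path(path).stem
    return df[FOOTPRINT_COLUMNS]


class PsiteOffsetTable:
    """Per-read-length offset from the read 5' end to the first nt of the
    P-site codon."""

    def __init__(self, offsets: Mapping[int, int]):
        for length, off in offsets.items():
            if not (0 <= off < length):
                raise ValueError(f"offset {off} for length {length} not in [0, length)")
        self._offsets = {int(k): int(v) for k, v in offsets.items()}

    def __getitem__(self, read_length: int) -> int:
        return self._offsets[read_length]

    def __contains__(self, read_length: int) -> bool:
        return read_length in self._offsets

    def lengths(self) -> set[int]:
        return set(self._offsets)

    def as_dict(self) -> dict[int, int]:
        return dict(self._offsets)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PsiteOffsetTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["read_length"].astype(int), df["offset"].astype(int))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._offsets.items()), columns=["read_length", "offset"]
        ).to_csv(path, sep="\t", index=False)


def filter_read_lengths(
    footprints: pd.DataFrame, keep: Iterable[int] | None = None
) -> pd.DataFrame:
    """Retain footprints whose length is in the keep-set (default 20-23 and
    27-32 nt); per-length retention counts are logged."""
    keep_set = DEFAULT_KEEP_LENGTHS if keep is None else frozenset(int(k) for k in keep)
    mask = footprints["read_length"].isin(keep_set)
    out = footprints.loc[mask].reset_index(drop=True)
    by_len = footprints.groupby("read_length")["count"].sum()
    for length, n in by_len.items():
        logger.info("read length %d: %s (%d reads)", length,
                    "kept" if length in keep_set else "dropped", n)
    if out.empty:
        warnings.warn("no footprints pass the read-length filter")
    return out


def assign_psites(
    footprints: pd.DataFrame,
    offsets: PsiteOffsetTable,
    transcripts: Mapping[str, Transcript],
    partitions: Mapping[str, RegionPartition] | None = None,
) -> pd.DataFrame:
    """Assign each footprint a P-site position, reading frame, and region.

    ``psite_pos = five_prime_pos + offset(read_length)``. Footprints on
    unknown transcripts or whose P-site falls outside the transcript are
    dropped (count logged). A missing offset for a present read length is a
    hard error.
    """
    present = set(footprints["read_length"].unique())
    missing = present - offsets.lengths()
    if missing:
        raise KeyError(f"no P-site offset for read length(s) {sorted(missing)}")

    df = footprints.copy()
    off = df["read_length"].map(offsets.as_dict())
    df["psite_pos"] = df["five_prime_pos"] + off

    known = df["transcript_id"].isin(transcripts.keys())
    if (~known).any():
        logger.info("dropping %d footprints on unknown transcripts", int(df.loc[~known, "count"].sum()))
    df = df.loc[known]

    cds_start = df["transcript_id"].map(lambda t: transcripts[t].cds_start)
    tx_len = df["transcript_id"].map(lambda t: len(transcripts[t]))
    inside = (df["psite_pos"] >= 0) & (df["psite_pos"] < tx_len)
    n_out = int(df.loc[~inside, "count"].sum())
    if n_out:
        logger.info("dropping %d footprints with P-site outside the transcript", n_out)
    df = df.loc[inside].copy()
    cds_start = cds_start.loc[df.index]

    df["frame"] = ((df["psite_pos"] - cds_start) % 3).astype(int)
    if partitions is not None:
        df["region"] = [
            partitions[t].label(p) if t in partitions else None
            for t, p in zip(df["transcript_id"], df["psite_pos"])
        ]
    return df.reset_index(drop=True)


def estimate_offsets(
    footprints: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    min_reads: int = 200,
) -> PsiteOffsetTable:
    """Estimate P-site offsets from start-codon occupancy when no calibrated
    table is supplied.

    For each read length, the offset is the modal distance from the read 5'
    end to ``cds_start`` among reads spanning the start codon (initiating
    ribosomes place their P-site on the AUG). Lengths with fewer than
    ``min_reads`` qualifying reads inherit the nearest estimated length's
    offset.
    """
    cds_start = footprints["transcript_id"].map(
        lambda t: transcripts[t].cds_start if t in transcripts else np.nan
    )
    d = cds_start - footprints["five_prime_pos"]
    spans = (d >= 0) & (d < footprints["read_length"])
    qual = footprints.loc[spans].assign(dist=d[spans].astype(int))

    estimated: dict[int, int] = {}
    support: dict[int, int] = {}
    for length, grp in qual.groupby("read_length"):
        n = int(grp["count"].sum())
        support[int(length)] = n
        if n >= min_reads:
            mode = grp.groupby("dist")["count"].sum().idxmax()
            estimated[int(length)] = int(mode)

    if not estimated:
        raise ValueError(
            "no read length has enough start-codon-spanning reads to estimate "
            "offsets; supply a calibrated offset table"
        )

    out = dict(estimated)
    for length in sorted(set(footprints["read_length"].astype(int))):
        if length not in out:
            nearest = min(estimated, key=lambda l: (abs(l - length), l))
            out[length] = estimated[nearest]
            warnings.warn(
                f"read length {length}: only {support.get(length, 0)} qualifying reads; "
                f"offset inherited from length {nearest}"
            )
    return PsiteOffsetTable(out)


def metagene_profile(
    psites: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    window_start: tuple[int, int] = (-25, 80),
    window_stop: tuple[int, int] = (-25, 80),
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """Metagene profile of P-site counts around the start and stop codons.

    Distances from start: ``psite_pos - cds_start`` (AUG first nt = 0).
    Distances from stop: ``psite_pos - (cds_end - 1)`` — the last sense
    nucleotide is 0, so the stop codon occupies distances 1..3 and the 3'-UTR
    is strictly "distance > 0". Counts in both windows are normalized by the
    summed count over both windows, so the returned fractions jointly sum
    to 1. With ``pool_replicates=False`` each library is normalized
    separately.

    Returns a tidy frame: ``library_id, anchor, distance, count, fraction``
    (``library_id == "pooled"`` when pooling).
    """
    df = psites[psites["transcript_id"].isin(transcripts.keys())].copy()
    utr_ok = df["transcript_id"].map(lambda t: transcripts[t].has_utr_annotation)
    df = df.loc[utr_ok]
    cds_start = df["transcript_id"].map(lambda t: transcripts[t].cds_start)
    cds_end = df["transcript_id"].map(lambda t: transcripts[t].cds_end)
    df["d_start"] = df["psite_pos"] - cds_start
    df["d_stop"] = df["psite_pos"] - (cds_end - 1)
    if pool_replicates:
        df["library_id"] = "pooled"

    pieces = []
    for anchor, col, (lo, hi) in (
        ("start", "d_start", window_start),
        ("stop", "d_stop", window_stop),
    ):
        sel = df[(df[col] >= lo) & (df[col] <= hi)]
        counts = (
            sel.groupby(["library_id", col])["count"].sum().rename("count").reset_index()
        )
        counts = counts.rename(columns={col: "distance"})
        counts["anchor"] = anchor
        # densify so flat stretches of zero appear explicitly
        full = pd.MultiIndex.from_product(
            [counts["library_id"].unique() if not counts.empty else df["library_id"].unique(),
             range(lo, hi + 1)],
            names=["library_id", "distance"],
        )
        counts = (
            counts.set_index(["library_id", "distance"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
        counts["anchor"] = anchor
        pieces.append(counts)
    prof = pd.concat(pieces, ignore_index=True)
    totals = prof.groupby("library_id")["count"].transform("sum")
    prof["fraction"] = np.where(totals > 0, prof["count"] / totals, 0.0)
    return prof[["library_id", "anchor", "distance", "count", "fraction"]]


def region_frame_counts(psites: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts of P-sites by library, region, and frame, with the
    derived percentages of the region-occupancy analysis.

    Returns one row per (library, region, frame) with ``count``, plus
    ``region_pct`` (the region's share of the library total, summed over
    frames, repeated on each frame row) and ``frame0_pct_in_region``.
    """
    df = psites.dropna(subset=["region"])
    counts = (
        df.groupby(["library_id", "region", "frame"])["count"]
        .sum()
        .reset_index(name="count")
    )
    # densify over all labels/frames present
    libs = counts["library_id"].unique()
    idx = pd.MultiIndex.from_product(
        [libs, REGION_LABELS, (0, 1, 2)], names=["library_id", "region", "frame"]
    )
    counts = (
        counts.set_index(["library_id", "region", "frame"])
        .reindex(idx, fill_value=0)
        .reset_index()
    )
    lib_tot = counts.groupby("library_id")["count"].transform("sum")
    region_tot = counts.groupby(["library_id", "region"])["count"].transform("sum")
    frame0 = counts.groupby(["library_id", "region"])["count"].transform(
        lambda s: s.iloc[0]
    )  # frame rows are ordered 0,1,2 within each group
    counts["region_pct"] = np.where(lib_tot > 0, 100.0 * region_tot / lib_tot, 0.0)
    counts["frame0_pct_in_region"] = np.where(
        region_tot > 0, 100.0 * frame0 / region_tot, np.nan
    )
    return counts


def compare_region_occupancy(
    region_counts: pd.DataFrame, strain_of: Mapping[str, str]
) -> pd.DataFrame:
    """Compare per-replicate region percentages between strains.

    ``region_counts`` is the output of :func:`region_frame_counts`; each
    library is one replicate observation of its strain. For every region and
    strain pair, a two-sided Welch t-test on the libraries' region
    percentages, BH-adjusted across the whole family. Returns one row per
    (region, strain pair).
    """
    from itertools import combinations

    from ribostop.stats import attach_bh, unpaired_t

    pct = (
        region_counts[region_counts["frame"] == 0]
        .assign(strain=lambda d: d["library_id"].map(strain_of))
        .loc[:, ["strain", "library_id", "region", "region_pct"]]
    )
    results, rows = [], []
    for region, sub in pct.groupby("region"):
        by_strain = {s: g["region_pct"].to_numpy() for s, g in sub.groupby("strain")}
        for a, b in combinations(sorted(by_strain), 2):
            if min(by_strain[a].size, by_strain[b].size) < 2:
                continue
            res = unpaired_t(by_strain[a], by_strain[b])
            results.append(res)
            rows.append((region, a, b, float(np.mean(by_strain[a])),
                         float(np.mean(by_strain[b]))))
    attach_bh(results)
    return pd.DataFrame(
        {
            "region": [r[0] for r in rows],
            "strain_a": [r[1] for r in rows],
            "strain_b": [r[2] for r in rows],
            "mean_pct_a": [r[3] for r in rows],
            "mean_pct_b": [r[4] for r in rows],
            "statistic": [t.statistic for t in results],
            "pvalue": [t.pvalue for t in results],
            "padj": [t.padj for t in results],
        }
    )


def frame0_share(psites: pd.DataFrame, region: str | None = None) -> float:
    """Fraction of P-sites in frame 0, optionally restricted to one region."""
    df = psites if region is None else psites[psites["region"] == region]
    tot = df["count"].sum()
    if tot == 0:
        return float("nan")
    return float(df.loc[df["frame"] == 0, "count"].sum() / tot)
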