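"""Transcript models, mRNA region partition, and the gene-overlap filter.

Coordinates are 0-based, half-open, in transcript space. The CDS interval
``[cds_start, cds_end)`` covers the start codon through the last sense codon;
the stop codon occupies ``[cds_end, cds_end + 3)`` and is counted as part of
the 3'-UTR, so "CDS length" never includes it.

Two distinct "extension" conventions coexist on purpose:

``rt_extension``
    From the canonical stop codon (inclusive) to the next in-frame stop codon
    (exclusive). This is the region a readthrough ribosome traverses and the
    denominator region of the readthrough-efficiency statistic.
``fig4_extension``
    From the end of the 9-nt stop window to the end of ``rt_extension``; used
    for region-occupancy percentages where the stop codon and its flanks are
    accounted separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: canonical region labels, in 5'->3' order
REGION_LABELS = (
    "five_utr",
    "start_window",
    "cds_body",
    "stop_window",
    "fig4_extension",
    "distal_3utr",
)

TABLE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "gene_start",
    "gene_end",
    "strand",
    "utr5_len",
    "cds_len",
    "utr3_len",
]


def _normalize_seq(seq: str) -> str:
    """Uppercase and collapse RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneSpan:
    """Genomic interval of the parent gene, used only by the overlap filter."""

    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class Transcript:
    """A spliced mRNA with an annotated CDS interval.

    ``cds_start`` is the transcript offset of the A of the annotated AUG;
    ``cds_end`` is the exclusive end of the last sense codon, so the stop
    codon (when annotated) sits at ``[cds_end, cds_end + 3)``.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    gene_span: GeneSpan | None = None
    gene_id: str | None = None
    has_utr_annotation: bool = True

    def __post_init__(self) -> None:
        self.sequence = _normalize_seq(self.sequence)
        cds_len = self.cds_end - self.cds_start
        if cds_len <= 0 or cds_len % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {cds_len} must be positive and divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        """3'-UTR length, stop codon included."""
        return len(self.sequence) - self.cds_end

    @property
    def stop_codon(self) -> str | None:
        codon = self.sequence[self.cds_end : self.cds_end + 3]
        return codon if len(codon) == 3 else None

    def check_stop(self) -> bool:
        """True when the codon after the CDS is a stop codon."""
        return self.stop_codon in STOP_CODONS


@dataclass
class RegionPartition:
    """Disjoint tiling of a transcript into the six analysis regions.

    All intervals are half-open ``(start, end)`` pairs; empty intervals have
    ``start == end``. ``rt_extension`` overlaps ``stop_window`` by
    construction (the stop codon belongs to both bookkeeping schemes).
    """

    transcript_id: str
    five_utr: tuple[int, int]
    start_window: tuple[int, int]
    cds_body: tuple[int, int]
    stop_window: tuple[int, int]
    fig4_extension: tuple[int, int]
    distal_3utr: tuple[int, int]
    rt_extension: tuple[int, int]
    open_extension: bool = False
    cds_start: int = 0
    cds_end: int = 0

    @property
    def rt_extension_length(self) -> int:
        return self.rt_extension[1] - self.rt_extension[0]

    def tiling(self) -> list[tuple[int, int]]:
        """The six disjoint intervals in 5'->3' order."""
        return [
            self.five_utr,
            self.start_window,
            self.cds_body,
            self.stop_window,
            self.fig4_extension,
            self.distal_3utr,
        ]

    def label(self, pos: int) -> str | None:
        """Region label for a transcript position, or None if out of range."""
        for name, (lo, hi) in zip(REGION_LABELS, self.tiling()):
            if lo <= pos < hi:
                return name
        return None


def find_next_inframe_stop(transcript: Transcript) -> int | None:
    """Offset of the first in-frame stop codon downstream of the canonical one.

    Scans codons at ``cds_end + 3k`` for ``k >= 1`` (the codon at ``cds_end``
    is the canonical stop itself) and returns the offset of the first stop
    triplet, or ``None`` when no downstream in-frame stop fits in the
    transcript.
    """
    seq = transcript.sequence
    j = transcript.cds_end + 3
    while j + 3 <= len(seq):
        if seq[j : j + 3] in STOP_CODONS:
            return j
        j += 3
    return None


def partition_regions(transcript: Transcript) -> RegionPartition:
    """Partition a transcript into the six disjoint analysis regions.

    The start window spans the AUG plus 3 flanking nt each side, the stop
    window the stop codon plus 3 flanking nt each side (both truncated at
    transcript boundaries; the windows take priority over 5'-UTR/CDS body so
    the six regions tile the transcript exactly once). Degenerate transcripts
    yield truncated, never negative, intervals.
    """
    L = len(transcript.sequence)
    cs, ce = transcript.cds_start, transcript.cds_end

    start_lo = max(0, cs - 3)
    start_hi = min(L, cs + 6)
    stop_lo = max(start_hi, ce - 3)
    stop_hi = min(L, ce + 6)

    next_stop = find_next_inframe_stop(transcript)
    if next_stop is None:
        # run to the last complete in-frame codon; flagged for exclusion
        rt_hi = ce + 3 * ((L - ce) // 3)
        open_extension = True
    else:
        rt_hi = next_stop
        open_extension = False

    fig4_lo = min(stop_hi, L)
    fig4_hi = max(fig4_lo, min(rt_hi, L))

    return RegionPartition(
        transcript_id=transcript.id,
        five_utr=(0, start_lo),
        start_window=(start_lo, start_hi),
        cds_body=(start_hi, stop_lo),
        stop_window=(stop_lo, stop_hi),
        fig4_extension=(fig4_lo, fig4_hi),
        distal_3utr=(fig4_hi, L),
        rt_extension=(ce, rt_hi),
        open_extension=open_extension,
        cds_start=cs,
        cds_end=ce,
    )


def load_transcripts(
    fasta_path: str | Path, table_path: str | Path
) -> dict[str, Transcript]:
    """Load transcripts from a FASTA plus a transcript table TSV.

    The table carries ``transcript_id, gene_id, chrom, gene_start, gene_end,
    strand, utr5_len, cds_len, utr3_len``. Rows whose CDS length is not a
    positive multiple of 3 are skipped with a warning; ids present in the
    table but absent from the FASTA (or vice versa) raise. ``utr3_len``
    includes the stop codon. Rows with ``utr5_len`` and ``utr3_len`` both 0
    are loaded with ``has_utr_annotation=False`` and excluded from
    UTR-dependent analyses downstream.
    """
    seqs = {rec.id: _normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(table_path, sep="\t", dtype={"transcript_id": str, "chrom": str})
    missing_cols = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"transcript table missing columns: {missing_cols}")

    table_ids = set(table["transcript_id"])
    fasta_only = sorted(set(seqs) - table_ids)
    table_only = sorted(table_ids - set(seqs))
    if fasta_only or table_only:
        raise ValueError(
            "FASTA/table id mismatch; "
            f"missing from table: {fasta_only[:10]}; missing from FASTA: {table_only[:10]}"
        )

    out: dict[str, Transcript] = {}
    for row in table.itertuples(index=False):
        tid = row.transcript_id
        cds_len = int(row.cds_len)
        if cds_len <= 0 or cds_len % 3 != 0:
            warnings.warn(
                f"{tid}: CDS length {cds_len} not a positive multiple of 3; record skipped"
            )
            continue
        cs = int(row.utr5_len)
        seq = seqs[tid]
        expected = cs + cds_len + int(row.utr3_len)
        if expected != len(seq):
            warnings.warn(
                f"{tid}: table lengths sum to {expected} but sequence is {len(seq)} nt; skipped"
            )
            continue
        tr = Transcript(
            id=tid,
            sequence=seq,
            cds_start=cs,
            cds_end=cs + cds_len,
            gene_span=GeneSpan(str(row.chrom), int(row.gene_start), int(row.gene_end), str(row.strand)),
            gene_id=str(row.gene_id),
            has_utr_annotation=(int(row.utr5_len) > 0 or int(row.utr3_len) > 0),
        )
        if tr.utr3_len >= 3 and not tr.check_stop():
            logger.warning("%s: codon after CDS is %s, not a stop codon", tid, tr.stop_codon)
        out[tid] = tr
    return out


def write_transcript_table(transcripts: Mapping[str, Transcript], path: str | Path) -> None:
    """Write the transcript table TSV consumed by :func:`load_transcripts`."""
    rows = []
    for tr in transcripts.values():
        gs = tr.gene_span
        rows.append(
            {
                "transcript_id": tr.id,
                "gene_id": tr.gene_id or tr.id,
                "chrom": gs.chrom if gs else "chrU",
                "gene_start": gs.start if gs else 0,
                "gene_end": gs.end if gs else len(tr.sequence),
                "strand": gs.strand if gs else "+",
                "utr5_len": tr.utr5_len,
                "cds_len": tr.cds_len,
                "utr3_len": tr.utr3_len,
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_gtf_table(gtf_path: str | Path) -> pd.DataFrame:
    """Map a GTF annotation to the transcript-table dialect.

    Only ``transcript``, ``exon`` and ``CDS`` features are read; 1-based
    closed GTF coordinates are converted to 0-based half-open. UTR lengths
    are derived from the exon/CDS geometry in transcript space; the GTF CDS
    is assumed stop-exclusive (the common convention).
    """
    recs: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in {"transcript", "exon", "CDS"}:
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            rec = recs.setdefault(
                tid,
                {"gene_id": attrs.get("gene_id", tid), "chrom": f[0], "strand": f[6],
                 "exons": [], "cds": []},
            )
            start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> 0-based half-open
            if f[2] == "exon":
                rec["exons"].append((start, end))
            elif f[2] == "CDS":
                rec["cds"].append((start, end))

    rows = []
    for tid, rec in recs.items():
        exons = sorted(rec["exons"])
        cds = sorted(rec["cds"])
        if not exons or not cds:
            warnings.warn(f"{tid}: GTF record lacks exon or CDS features; skipped")
            continue
        tx_len = sum(e - s for s, e in exons)
        cds_len = sum(e - s for s, e in cds)
        # transcript-space offset of the CDS start: exonic nt strictly 5' of the CDS
        if rec["strand"] == "-":
            cds_edge = cds[-1][1]
            utr5 = sum(max(0, e - max(s, cds_edge)) for s, e in exons)
        else:
            cds_edge = cds[0][0]
            utr5 = sum(max(0, min(e, cds_edge) - s) for s, e in exons)
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": rec["gene_id"],
                "chrom": rec["chrom"],
                "gene_start": exons[0][0],
                "gene_end": exons[-1][1],
                "strand": rec["strand"],
                "utr5_len": utr5,
                "cds_len": cds_len,
                "utr3_len": tx_len - utr5 - cds_len,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def overlap_filter(
    transcripts: Iterable[Transcript], max_overlap: int = 18
) -> set[str]:
    """Ids of transcripts whose gene overlaps every other same-strand gene by
    fewer than ``max_overlap`` nt.

    Genes sharing ``gene_id`` are never compared against each other (multiple
    isoforms of one gene are not self-overlaps). Opposite-strand overlap is
    ignored. The relation is symmetric: if A excludes B, B excludes A.
    """
    trs = [t for t in transcripts]
    kept: set[str] = set()
    spans: list[tuple[Transcript, GeneSpan]] = []
    for t in trs:
        if t.gene_span is None:
            warnings.warn(f"{t.id}: no gene_span; excluded from overlap filter")
            continue
        spans.append((t, t.gene_span))
        kept.add(t.id)

    for i, (ti, si) in enumerate(spans):
        for tj, sj in spans[i + 1 :]:
            if si.chrom != sj.chrom or si.strand != sj.strand:
                continue
            if ti.gene_id is not None and ti.gene_id == tj.gene_id:
                continue
            ov = min(si.end, sj.end) - max(si.start, sj.start)
            if ov >= max_overlap:
                kept.discard(ti.id)
                kept.discard(tj.id)
    return kept
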