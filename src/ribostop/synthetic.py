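"""Synthetic transcriptomes, ribosome footprints, and RNA counts with full
ground truth.

The generator emulates the study design the analysis assumes: a small number
of strains (e.g. a wild type and mutants) with three replicate libraries
each; footprints concentrated in the CDS with high frame-0 fidelity;
extension-region occupancy proportional to a per-transcript readthrough rate
``rho`` (scaled per strain); distal 3'-UTR occupancy at ``rho**2`` (double
readthrough past the second stop); NB-distributed RNA counts; and planted,
re-detectable sequence features (uORFs, poly(A)/oligo(U) tracts, chosen stop
codons, controlled extension lengths).

Everything is deterministic given the master seed. Per-transcript base
readthrough rates are log-normal; extension occupancy is modeled as
density-proportional, so the true ``rho`` and the readthrough-efficiency
statistic are estimands of each other.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ribostop import features as rfeat
from ribostop.annotation import (
    STOP_CODONS,
    GeneSpan,
    Transcript,
    partition_regions,
    write_transcript_table,
)
from ribostop.psite import PsiteOffsetTable

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: default P-site offsets per admitted read length (calibration-table shape)
DEFAULT_OFFSETS = {20: 8, 21: 9, 22: 9, 23: 10, 27: 11, 28: 12, 29: 12, 30: 13, 31: 13, 32: 14}


@dataclass
class StrainConfig:
    """Per-strain global effects relative to the simulation baseline."""

    name: str
    rt_multiplier: float = 1.0  # scales every transcript's readthrough rate
    te_effect_frac: float = 0.0  # fraction of genes with a TE effect
    te_effect_log2: float = 0.0  # magnitude (sign randomized per gene)
    rna_effect_frac: float = 0.0
    rna_effect_log2: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror a compact version of the emulated design: three strains
    (control, a neutral deletion, and a readthrough-elevated double mutant)
    with three replicates each, yeast-like transcript geometry, 95% frame-0
    fidelity, and log-normal per-transcript readthrough rates centered near
    1-2%.
    """

    n_transcripts: int = 300
    utr5_len_range: tuple[int, int] = (24, 60)
    cds_codons_range: tuple[int, int] = (80, 250)
    extension_codons_range: tuple[int, int] = (2, 12)  # distance to next in-frame stop, codons
    distal_utr_range: tuple[int, int] = (30, 150)  # nt beyond the extension stop
    strains: tuple[StrainConfig, ...] = (
        StrainConfig("wt"),
        StrainConfig("mut1"),
        StrainConfig("mut2", rt_multiplier=3.0),
    )
    replicates: int = 3
    frame_fidelity: float = 0.95
    rho_log10_mean: float = -1.7  # median rho ~ 0.02
    rho_log10_sd: float = 0.35
    abundance_log10_sd: float = 0.4
    te_log10_sd: float = 0.15
    ribo_reads_per_transcript: float = 300.0  # expected CDS footprints at abundance 1, TE 1
    rna_reads_per_transcript: float = 300.0
    nb_dispersion: float = 0.05
    background_rate: float = 0.0005  # off-signal footprints per nt per library
    read_lengths: tuple[int, ...] = (20, 21, 22, 23, 27, 28, 29, 30, 31, 32)
    read_length_probs: tuple[float, ...] = (0.03, 0.04, 0.05, 0.05, 0.08, 0.3, 0.25, 0.1, 0.06, 0.04)
    offsets: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    p_upstream_uorf: float = 0.15
    p_overlapping_uorf: float = 0.08
    p_polyA_5utr: float = 0.1
    p_polyA_3utr: float = 0.1
    p_oligoU_5utr: float = 0.08
    p_oligoU_3utr: float = 0.08
    stop_codon_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TAA": 0.45, "TAG": 0.25, "TGA": 0.30}
    )
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["strains"] = [asdict(s) for s in self.strains]
        d["offsets"] = {str(k): v for k, v in dict(self.offsets).items()}
        d["stop_codon_probs"] = dict(self.stop_codon_probs)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def _clean_utr5(rng, length, want_uorf, want_polyA, want_oligoU, cds_first_nt="A",
                max_tries: int = 200) -> str:
    """A 5'-UTR with exactly the requested feature content.

    ``want_uorf`` is None, "upstream", or "overlapping". Rejection-sampled so
    the scanners detect exactly the planted features (the poly(A) scan
    includes the A of the main AUG, passed as ``cds_first_nt``).
    """
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if want_uorf == "upstream" and length >= 12:
            # AUG + >=1 sense codon + stop, fully inside the UTR, in-frame
            body_codons = int(rng.integers(1, max(2, (length - 9) // 3)))
            block = "ATG" + _random_sense_codons(rng, body_codons) + "TAA"
            start = int(rng.integers(0, length - len(block) + 1))
            seq = seq[:start] + block + seq[start + len(block):]
        elif want_uorf == "overlapping" and length >= 5:
            # AUG out of frame with the main ORF, close to the boundary so no
            # stop intervenes before cds_start
            delta = int(rng.choice([4, 5, 7, 8]))
            if delta <= length:
                start = length - delta
                seq = seq[:start] + "ATG" + seq[start + 3:]
        if want_polyA and length >= 10:
            start = int(rng.integers(0, length - 10 + 1))
            seq = seq[:start] + "A" * 10 + seq[start + 10:]
        if want_oligoU and length >= 7:
            start = int(rng.integers(0, length - 7 + 1))
            seq = seq[:start] + "T" * 7 + seq[start + 7:]

        tr = Transcript(id="tmp", sequence=seq + "ATGGCTTCTTAA", cds_start=length,
                        cds_end=length + 9)
        uorfs = rfeat.find_uorfs(tr)
        kinds = {u.kind for u in uorfs}
        if want_uorf is None and uorfs:
            continue
        if want_uorf == "upstream" and kinds != {"upstream"}:
            continue
        if want_uorf == "overlapping" and kinds != {"overlapping"}:
            continue
        if rfeat.scan_polyA(seq + cds_first_nt) != bool(want_polyA):
            continue
        if rfeat.scan_oligoU(seq) != bool(want_oligoU):
            continue
        return seq
    raise RuntimeError("could not construct a 5'-UTR with the requested features")


def _clean_utr3(rng, stop_codon, ext_codons, distal_len, want_polyA, want_oligoU,
                max_tries: int = 200) -> str:
    """A 3'-UTR (stop codon included): canonical stop, ``ext_codons - 1``
    sense codons, the extension-terminating stop, then a distal segment.
    No accidental in-frame stop precedes the planted one; tract content
    matches the flags exactly."""
    for _ in range(max_tries):
        ext_body = _random_sense_codons(rng, ext_codons - 1)
        distal = _random_seq(rng, distal_len)
        if want_polyA and distal_len >= 10:
            start = int(rng.integers(0, distal_len - 10 + 1))
            distal = distal[:start] + "A" * 10 + distal[start + 10:]
        if want_oligoU and distal_len >= 7:
            start = int(rng.integers(0, distal_len - 7 + 1))
            distal = distal[:start] + "T" * 7 + distal[start + 7:]
        utr3 = stop_codon + ext_body + "TAA" + distal
        if rfeat.scan_polyA(utr3) != bool(want_polyA):
            continue
        if rfeat.scan_oligoU(utr3) != bool(want_oligoU):
            continue
        return utr3
    raise RuntimeError("could not construct a 3'-UTR with the requested features")


def simulate_transcriptome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, Transcript], pd.DataFrame]:
    """Generate transcripts plus the per-transcript ground-truth table.

    Truth columns: planted feature flags, stop codon, extension length (nt,
    stop included), base readthrough rate ``rho``, relative abundance, base
    TE, and per-strain effect assignments (``te_effect_<strain>``,
    ``rna_effect_<strain>`` in log2 units; 0 where unaffected).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.extension_codons_range
    if lo < 1 or min(config.distal_utr_range) < 0:
        raise ValueError("extension needs at least one codon and a nonnegative distal 3'-UTR")

    stop_names = list(config.stop_codon_probs)
    stop_p = np.array([config.stop_codon_probs[s] for s in stop_names], dtype=float)
    stop_p = stop_p / stop_p.sum()

    transcripts: dict[str, Transcript] = {}
    rows = []
    genome_cursor = 0
    for i in range(config.n_transcripts):
        tid = f"SYN{i:04d}"
        utr5_len = int(rng.integers(*config.utr5_len_range))
        n_codons = int(rng.integers(*config.cds_codons_range))
        ext_codons = int(rng.integers(lo, hi + 1))
        distal_len = int(rng.integers(*config.distal_utr_range))
        stop_codon = str(rng.choice(stop_names, p=stop_p))

        u = rng.uniform()
        if u < config.p_upstream_uorf:
            uorf = "upstream"
        elif u < config.p_upstream_uorf + config.p_overlapping_uorf:
            uorf = "overlapping"
        else:
            uorf = None
        polyA5 = rng.uniform() < config.p_polyA_5utr
        polyA3 = rng.uniform() < config.p_polyA_3utr
        oligoU5 = rng.uniform() < config.p_oligoU_5utr
        oligoU3 = rng.uniform() < config.p_oligoU_3utr

        utr5 = _clean_utr5(rng, utr5_len, uorf, polyA5, oligoU5)
        cds = "ATG" + _random_sense_codons(rng, n_codons - 1)
        utr3 = _clean_utr3(rng, stop_codon, ext_codons, distal_len, polyA3, oligoU3)
        seq = utr5 + cds + utr3

        gene_len = len(seq)
        span = GeneSpan("chrS", genome_cursor, genome_cursor + gene_len, "+")
        genome_cursor += gene_len + 200  # non-overlapping by construction

        tr = Transcript(
            id=tid, sequence=seq, cds_start=utr5_len, cds_end=utr5_len + 3 * n_codons,
            gene_span=span, gene_id=tid,
        )
        transcripts[tid] = tr

        rho = float(10 ** rng.normal(config.rho_log10_mean, config.rho_log10_sd))
        abundance = float(10 ** rng.normal(0.0, config.abundance_log10_sd))
        te = float(10 ** rng.normal(0.0, config.te_log10_sd))
        row = {
            "transcript_id": tid,
            "utr5_len": utr5_len,
            "cds_len": 3 * n_codons,
            "ext_length": 3 * ext_codons,
            "utr3_len": len(utr3),
            "stop_codon": stop_codon,
            "uorf_class": uorf or "none",
            "polyA_5utr": polyA5,
            "polyA_3utr": polyA3,
            "oligoU_5utr": oligoU5,
            "oligoU_3utr": oligoU3,
            "rho": min(rho, 0.5),
            "abundance": abundance,
            "te": te,
        }
        rows.append(row)

    truth = pd.DataFrame(rows).set_index("transcript_id")
    # per-strain effect assignments
    for sc in config.strains:
        te_eff = np.zeros(len(truth))
        rna_eff = np.zeros(len(truth))
        if sc.te_effect_frac > 0 and sc.te_effect_log2 != 0:
            n_eff = int(round(sc.te_effect_frac * len(truth)))
            idx = rng.choice(len(truth), size=n_eff, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_eff)
            te_eff[idx] = signs * sc.te_effect_log2
        if sc.rna_effect_frac > 0 and sc.rna_effect_log2 != 0:
            n_eff = int(round(sc.rna_effect_frac * len(truth)))
            idx = rng.choice(len(truth), size=n_eff, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_eff)
            rna_eff[idx] = signs * sc.rna_effect_log2
        truth[f"te_effect_{sc.name}"] = te_eff
        truth[f"rna_effect_{sc.name}"] = rna_eff
        truth[f"rho_{sc.name}"] = np.minimum(truth["rho"] * sc.rt_multiplier, 0.9)
    return transcripts, truth


def simulate_footprints(
    transcripts: Mapping[str, Transcript],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ribosome footprints for every strain x replicate library.

    Per transcript: CDS P-site count ~ Poisson(depth * abundance * TE),
    uniform over CDS codons, frame 0 with probability ``frame_fidelity``
    (otherwise jittered +-1 nt); extension frame-0 density = CDS frame-0
    density x rho(strain); distal 3'-UTR density = CDS frame-0 density x
    rho**2; plus uniform background at ``background_rate`` per nt. Raw
    records carry 5' positions = psite - offset(length). Footprints whose 5'
    end would fall before the transcript start are dropped.

    Returns the footprint frame (transcript_id, five_prime_pos, read_length,
    count, library_id) with library ids ``<strain>_rep<k>``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    offsets = dict(config.offsets)
    lengths = np.array(config.read_lengths)
    length_p = np.array(config.read_length_probs, dtype=float)
    length_p = length_p / length_p.sum()
    off_of = np.array([offsets[l] for l in lengths])

    parts = {tid: partition_regions(tr) for tid, tr in transcripts.items()}
    all_rows = []
    for sc in config.strains:
        for rep in range(1, config.replicates + 1):
            lib = f"{sc.name}_rep{rep}"
            psites_list = []
            frames_list = []
            tids_list = []
            for tid, tr in transcripts.items():
                t = truth.loc[tid]
                part = parts[tid]
                te = t["te"] * 2.0 ** t.get(f"te_effect_{sc.name}", 0.0)
                abun = t["abundance"] * 2.0 ** t.get(f"rna_effect_{sc.name}", 0.0)
                rho = float(t[f"rho_{sc.name}"])
                lam_cds = config.ribo_reads_per_transcript * abun * te
                n_cds = rng.poisson(lam_cds)
                cds_codon_starts = np.arange(tr.cds_start, tr.cds_end, 3)
                pos = rng.choice(cds_codon_starts, size=n_cds)
                in_frame = rng.uniform(size=n_cds) < config.frame_fidelity
                jitter = rng.choice([-1, 1], size=n_cds)
                pos = np.where(in_frame, pos, pos + jitter)

                f0_density = lam_cds * config.frame_fidelity / tr.cds_len
                ext_lo, ext_hi = part.rt_extension
                ext_starts = np.arange(ext_lo, ext_hi, 3)
                n_ext = rng.poisson(f0_density * rho * len(ext_starts) * 3)
                ext_pos = rng.choice(ext_starts, size=n_ext) if len(ext_starts) else np.empty(0, int)

                distal_starts = np.arange(ext_hi, len(tr.sequence) - 2, 3)
                n_dist = rng.poisson(f0_density * rho**2 * len(distal_starts) * 3)
                dist_pos = (
                    rng.choice(distal_starts, size=n_dist) if len(distal_starts) else np.empty(0, int)
                )

                n_bg = rng.poisson(config.background_rate * len(tr.sequence))
                bg_pos = rng.integers(0, len(tr.sequence), size=n_bg)

                p = np.concatenate([pos, ext_pos, dist_pos, bg_pos]).astype(int)
                psites_list.append(p)
                tids_list.append(np.repeat(tid, p.size))
            psites = np.concatenate(psites_list)
            tids = np.concatenate(tids_list)
            li = rng.choice(len(lengths), size=psites.size, p=length_p)
            five_prime = psites - off_of[li]
            ok = five_prime >= 0
            df = pd.DataFrame(
                {
                    "transcript_id": tids[ok],
                    "five_prime_pos": five_prime[ok],
                    "read_length": lengths[li[ok]],
                }
            )
            df = (
                df.groupby(["transcript_id", "five_prime_pos", "read_length"])
                .size()
                .reset_index(name="count")
            )
            df["library_id"] = lib
            all_rows.append(df)
    return pd.concat(all_rows, ignore_index=True)[
        ["transcript_id", "five_prime_pos", "read_length", "count", "library_id"]
    ]


def simulate_rna_counts(
    transcripts: Mapping[str, Transcript],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """NB-distributed RNA-Seq counts, genes x libraries (``<strain>_rep<k>_rna``).

    mean = depth * abundance * 2^(strain RNA effect); NB via gamma-Poisson
    with gamma shape 1/dispersion, independent across replicates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tids = list(truth.index)
    cols = {}
    alpha = config.nb_dispersion
    for sc in config.strains:
        mean = (
            config.rna_reads_per_transcript
            * truth["abundance"].to_numpy()
            * 2.0 ** truth[f"rna_effect_{sc.name}"].to_numpy()
        )
        for rep in range(1, config.replicates + 1):
            if alpha > 0:
                lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
            else:
                lam = mean
            cols[f"{sc.name}_rep{rep}_rna"] = rng.poisson(lam)
    return pd.DataFrame(cols, index=pd.Index(tids, name="transcript_id"))


def strain_of_library(config: SimConfig) -> dict[str, str]:
    """library_id -> strain mapping for the footprint libraries."""
    return {
        f"{sc.name}_rep{r}": sc.name
        for sc in config.strains
        for r in range(1, config.replicates + 1)
    }


def write_fixture(
    out_dir: str | Path,
    config: SimConfig,
) -> dict:
    """Generate a complete fixture on disk and return the manifest.

    Emits: ``transcripts.fasta``, ``transcripts.tsv``, ``offsets.tsv``,
    ``footprints.tsv``, ``rna_counts.tsv``, ``truth.tsv``, and
    ``manifest.json`` (config hash, seed, file list, row counts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    transcripts, truth = simulate_transcriptome(config, rng)
    footprints = simulate_footprints(transcripts, truth, config, rng)
    rna = simulate_rna_counts(transcripts, truth, config, rng)

    with open(out / "transcripts.fasta", "w") as fh:
        for tid, tr in transcripts.items():
            fh.write(f">{tid}\n{tr.sequence}\n")
    write_transcript_table(transcripts, out / "transcripts.tsv")
    PsiteOffsetTable(dict(config.offsets)).to_tsv(out / "offsets.tsv")
    footprints.to_csv(out / "footprints.tsv", sep="\t", index=False)
    rna.to_csv(out / "rna_counts.tsv", sep="\t")
    truth.to_csv(out / "truth.tsv", sep="\t")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_transcripts": len(transcripts),
        "n_footprints": int(footprints["count"].sum()),
        "files": [
            "transcripts.fasta", "transcripts.tsv", "offsets.tsv",
            "footprints.tsv", "rna_counts.tsv", "truth.tsv",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
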