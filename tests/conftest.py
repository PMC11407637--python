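"""Shared fixtures: a compact synthetic experiment reused across test modules.

Everything is generated at test time from fixed seeds; nothing is read from
disk except files the tests themselves write to tmp paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ribostop import annotation, psite, synthetic


@pytest.fixture(scope="session")
def std_config() -> synthetic.SimConfig:
    """Standard study-shaped simulation: 3 strains x 3 replicates, one strain
    with 3x elevated readthrough, moderate coverage."""
    return synthetic.SimConfig(
        n_transcripts=150,
        seed=42,
        strains=(
            synthetic.StrainConfig("wt"),
            synthetic.StrainConfig("mut1"),
            synthetic.StrainConfig("mut2", rt_multiplier=3.0),
        ),
        ribo_reads_per_transcript=300,
    )


@pytest.fixture(scope="session")
def std_sim(std_config):
    """(transcripts, truth, footprints) for the standard config."""
    rng = np.random.default_rng(std_config.seed)
    transcripts, truth = synthetic.simulate_transcriptome(std_config, rng)
    footprints = synthetic.simulate_footprints(transcripts, truth, std_config, rng)
    return transcripts, truth, footprints


@pytest.fixture(scope="session")
def std_partitions(std_sim):
    transcripts, _, _ = std_sim
    return {tid: annotation.partition_regions(tr) for tid, tr in transcripts.items()}


@pytest.fixture(scope="session")
def std_psites(std_sim, std_partitions, std_config):
    transcripts, _, footprints = std_sim
    kept = psite.filter_read_lengths(footprints)
    offsets = psite.PsiteOffsetTable(dict(std_config.offsets))
    return psite.assign_psites(kept, offsets, transcripts, std_partitions)


@pytest.fixture(scope="session")
def std_strain_of(std_config):
    return synthetic.strain_of_library(std_config)


def random_transcript(rng: np.random.Generator) -> annotation.Transcript:
    """A random structurally valid transcript (no feature guarantees)."""
    utr5 = int(rng.integers(0, 40))
    codons = int(rng.integers(2, 60))
    utr3 = int(rng.integers(0, 90))
    seq = (
        "".join(rng.choice(list("ACGT"), size=utr5))
        + "ATG"
        + "".join(synthetic.SENSE_CODONS[i] for i in rng.integers(len(synthetic.SENSE_CODONS), size=codons - 1))
        + "".join(rng.choice(list("ACGT"), size=utr3))
    )
    return annotation.Transcript(
        id="rnd", sequence=seq, cds_start=utr5, cds_end=utr5 + 3 * codons,
        has_utr_annotation=utr3 > 0,
    )
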