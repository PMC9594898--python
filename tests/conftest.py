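"""Shared fixtures: read structure, synthetic genomes, junction-read batches."""

import numpy as np
import pytest

from insertmap.peaks import PipelineConfig
from insertmap.readprep import ReadStructure
from insertmap.simulate import (
    ReadSimConfig,
    RepeatFamilySpec,
    build_synthetic_genome,
    plant_insertions,
    simulate_junction_reads,
)

ADAPTER = "AGATACGGCGACCACCGAGATC"
PAYLOAD_END = "TTGTACACCCTAAGCCTCCGCC"
BARCODES = {"BC01": "ACGTGCTA", "BC02": "TGCACGAT"}


@pytest.fixture(scope="session")
def structure():
    return ReadStructure(adapter=ADAPTER, barcodes=BARCODES, umi_length=12,
                         payload_end=PAYLOAD_END, max_error_fraction=0.1)


def make_sim_config(**kw):
    base = dict(
        adapter=ADAPTER,
        payload_end=PAYLOAD_END,
        barcodes=BARCODES,
        umi_length=12,
        length_mean=400.0,
        length_sd=25.0,
        reads_per_site=8,
        quality_mean=15,
        seed=0,
    )
    base.update(kw)
    return ReadSimConfig(**base)


@pytest.fixture(scope="session")
def small_genome():
    """60 kb genome, one diverged repeat family, six planted insertions."""
    g = build_synthetic_genome(
        [RepeatFamilySpec("LINE_A", 1000, 4, 0.02)], [40_000, 20_000], seed=101
    )
    return plant_insertions(g, 6, "LV", 0.5, seed=102, min_distance=2500)


@pytest.fixture(scope="session")
def unique_genome():
    """Repeat-free 50 kb genome with five insertions in unique sequence."""
    g = build_synthetic_genome([], [50_000], seed=201)
    return plant_insertions(g, 5, "LV", 0.0, seed=202, min_distance=5000)


@pytest.fixture(scope="session")
def clean_reads(unique_genome):
    """Error-free junction reads: 5 sites x 20 molecules."""
    cfg = make_sim_config(reads_per_site=20, seed=7)
    return simulate_junction_reads(unique_genome, cfg)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
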