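"""Shared fixtures: one full-scale synthetic run reused across the suite.

The default run (5-Mb genome, 200 enhancers / 200 promoters / 400
background DHS, seed 1) is expensive enough that it is computed once per
session; smaller configurations are built per-test where isolation
matters.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromenh.pipeline import PipelineRun, run_synthetic
from chromenh.synthetic import (
    SimConfig,
    SyntheticGenome,
    simulate_annotation,
    simulate_expression,
    simulate_tags,
)

SEED = 1


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def default_run(default_config) -> PipelineRun:
    """Full pipeline on the default synthetic genome, seed 1."""
    return run_synthetic(default_config, seed=SEED)


@pytest.fixture(scope="session")
def default_expr(default_run):
    return simulate_expression(default_run.genome, SEED)


@pytest.fixture(scope="session")
def null_genome_and_tags():
    """Same study conditions but zero planted amplitude everywhere."""
    config = SimConfig(amplitude_scale=0.0)
    genome = simulate_annotation(config, SEED)
    tags = simulate_tags(genome, SEED)
    return genome, tags


def small_config(**overrides) -> SimConfig:
    """A light configuration for module-level integration tests."""
    base = dict(
        chrom_lengths={"chr1": 450_000, "chr2": 350_000},
        n_enhancers=12,
        n_promoters=12,
        n_background_dhs=24,
        n_background_tes=150,
        n_genes=30,
        n_background_candidates=6,
        replicates=(4, 4),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture()
def small_genome() -> SyntheticGenome:
    return simulate_annotation(small_config(), seed=7)
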