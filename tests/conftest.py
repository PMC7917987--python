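"""Shared fixtures: small simulated herds for unit tests and the
session-scoped replicate experiments behind the directional checks."""

from __future__ import annotations

import numpy as np
import pytest

from stepweight.data_io import PipelineConfig, run_pipeline
from stepweight.simulate import SimulationScenario, simulate_herd

REPLICATE_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def small_herd():
    """~160 animals, 200 SNPs: fast substrate for algebraic checks."""
    scn = SimulationScenario(
        n_founders=40, n_generations=4, n_offspring_per_gen=40,
        n_sires_per_gen=5, n_snps=200, n_chromosomes=2, seed=7,
    )
    return simulate_herd(scn)


@pytest.fixture(scope="session")
def tiny_herd():
    scn = SimulationScenario(
        n_founders=20, n_generations=3, n_offspring_per_gen=15,
        n_sires_per_gen=4, n_snps=60, n_chromosomes=2, seed=5,
    )
    return simulate_herd(scn)


def run_preset(scenario: str, strategy: str, seed: int, n_iter: int = 10):
    cfg = PipelineConfig(scenario=scenario, strategy=strategy,
                         n_iterations=n_iter, seed=seed)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def oligo_default_runs():
    """Default single-SNP weighting on the few-QTL preset, 10 seeds."""
    return {s: run_preset("oligogenic", "default", s) for s in REPLICATE_SEEDS}


@pytest.fixture(scope="session")
def oligo_window_runs():
    """Summed 75-SNP-window weighting on the few-QTL preset, 10 seeds."""
    return {s: run_preset("oligogenic", "window_summed", s) for s in REPLICATE_SEEDS}


@pytest.fixture(scope="session")
def poly_window_runs():
    """Summed 75-SNP-window weighting on the polygenic preset, 10 seeds."""
    return {s: run_preset("polygenic", "window_summed", s) for s in REPLICATE_SEEDS}


def random_pedigree(n: int, seed: int, p_unknown: float = 0.15):
    """Arbitrary acyclic pedigree allowing cross-generation, inbred matings."""
    from stepweight.pedigree import UNKNOWN_PARENT, PedigreeTable

    rng = np.random.default_rng(seed)
    ids = np.array([f"X{i}" for i in range(n)], dtype=object)
    sire = np.full(n, UNKNOWN_PARENT, dtype=object)
    dam = np.full(n, UNKNOWN_PARENT, dtype=object)
    year = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if rng.random() > p_unknown:
            sire[i] = ids[rng.integers(0, i)]
        if rng.random() > p_unknown and i > 1:
            cand = ids[rng.integers(0, i)]
            if cand != sire[i]:
                dam[i] = cand
        year[i] = 2000 + int(np.log2(i + 1))
    return PedigreeTable(ids, sire, dam, year)
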