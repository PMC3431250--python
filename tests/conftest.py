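"""Shared fixtures: small simulated populations reused across test modules.

Simulations are session-scoped (they dominate runtime) and fully seeded, so
the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flockld.datamodel import HaplotypeSet, MarkerMap, Pedigree
from flockld.simulate import SimConfig, sample_halfsib, simulate_population


def population_haplotypes(truth) -> HaplotypeSet:
    """Wrap the final Wright-Fisher generation as a HaplotypeSet."""
    H = truth.haplotypes
    carriers = [
        (f"ind_{i // 2 + 1}", "P" if i % 2 == 0 else "M") for i in range(H.shape[0])
    ]
    return HaplotypeSet(H, carriers, truth.markers)


@pytest.fixture(scope="session")
def small_constant_truth():
    """Constant Ne=60, small panel: cheap substrate for structural tests."""
    cfg = SimConfig(
        ne_trajectory=((0, 60),),
        n_chromosomes=3,
        snps_per_chromosome=120,
        candidate_snp_factor=4,
        n_sires=4,
        daughters_per_sire=15,
        seed=11,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def small_halfsib(small_constant_truth):
    cfg, truth = small_constant_truth
    return cfg, sample_halfsib(truth)


@pytest.fixture(scope="session")
def ne100_truth():
    """Constant Ne=100 population used by the Ne-recovery checks."""
    cfg = SimConfig(ne_trajectory=((0, 100),), seed=3)
    return cfg, simulate_population(cfg)


def toy_markers(n: int, chrom: int = 1, spacing_bp: int = 10_000) -> MarkerMap:
    return MarkerMap(
        np.array([f"s{k}" for k in range(n)], dtype=object),
        np.full(n, chrom),
        (np.arange(n) + 1) * spacing_bp,
    )


def make_pedigree(rows: list[tuple]) -> Pedigree:
    """rows of (id, sire, dam, birth_year) with None for unknown."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year"])
    )
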