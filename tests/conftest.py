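"""Shared fixtures: small hand-built pedigrees, random-pedigree factory,
and scaled-down registry simulations (session-scoped, they are reused by
many tests)."""

from __future__ import annotations

import numpy as np
import pytest

import pedkit as pk
from pedkit.simulate import SimulationConfig, simulate_registry


@pytest.fixture
def trio() -> pk.Pedigree:
    """Two founders and their offspring."""
    return pk.Pedigree.from_records([
        pk.PedigreeRecord("A", None, None, "male", 1985),
        pk.PedigreeRecord("B", None, None, "female", 1986),
        pk.PedigreeRecord("C", "A", "B", "male", 1990),
    ])


@pytest.fixture
def fullsib_mating() -> pk.Pedigree:
    """Full sibs from unrelated founders, mated: offspring F = 0.25."""
    return pk.Pedigree.from_records([
        pk.PedigreeRecord("A", None, None, "male", 1980),
        pk.PedigreeRecord("B", None, None, "female", 1980),
        pk.PedigreeRecord("S", "A", "B", "male", 1990),
        pk.PedigreeRecord("D", "A", "B", "female", 1990),
        pk.PedigreeRecord("X", "S", "D", "male", 2000),
    ])


def random_pedigree(seed: int, n: int = 250,
                    founder_rate: float = 0.12) -> pk.Pedigree:
    """Random valid pedigree: each animal draws parents among earlier
    animals, with some founder injection and occasional missing slots."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        if i < 8 or rng.random() < founder_rate:
            s = d = None
        else:
            s = f"a{rng.integers(0, i)}"
            d = f"a{rng.integers(0, i)}"
            if rng.random() < 0.1:
                s = None
            if d == s or rng.random() < 0.1:
                d = None
        recs.append(pk.PedigreeRecord(f"a{i}", s, d, "unknown", 1980 + i // 5))
    return pk.Pedigree.from_records(recs)


SMALL_REGISTRY_CONFIG = SimulationConfig(
    n_founders=300,
    births_per_year={y: 70 for y in range(1985, 2025)},
    sire_usage_concentration=1.5,
    p_male=0.08,
    seed=3,
)


@pytest.fixture(scope="session")
def small_registry():
    """A ~3k-animal registry simulation plus its ground truth."""
    return simulate_registry(SMALL_REGISTRY_CONFIG)


@pytest.fixture(scope="session")
def small_registry_pedigree(small_registry) -> pk.Pedigree:
    return small_registry[0]
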