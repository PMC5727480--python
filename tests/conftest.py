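"""Shared fixtures: tiny hand-built matrices/trees and a seeded mid-size
synthetic dataset (generated at test time, never stored)."""

from __future__ import annotations

import numpy as np
import pytest

from dispartime.datamodel import (
    ContinuousMatrix,
    DiscreteMatrix,
    Phylogeny,
    TaxonRecord,
    TimeBin,
    TimeBinSet,
)
from dispartime.simulate import SimulationConfig, make_dataset


def single(s: int) -> frozenset:
    return frozenset([s])


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_matrix() -> DiscreteMatrix:
    # one clean synapomorphy, one homoplastic character
    return DiscreteMatrix(
        taxa=list("ABCD"),
        states=[
            [single(0), single(0)],
            [single(0), single(1)],
            [single(1), single(0)],
            [single(1), single(1)],
        ],
    )


@pytest.fixture
def equal_bins() -> TimeBinSet:
    return TimeBinSet(
        [TimeBin("b1", 30.0, 20.0), TimeBin("b2", 20.0, 10.0), TimeBin("b3", 10.0, 0.0)]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """12-taxon synthetic clade, fixed seed, shared across the session."""
    cfg = SimulationConfig(n_tips=12, n_discrete=40, n_continuous=12)
    return make_dataset(cfg, seed=2024)


@pytest.fixture(scope="session")
def study_shaped_dataset():
    """Fixture with the full study dimensions (30 x 75 discrete + 31
    continuous, 30% missing)."""
    return make_dataset(SimulationConfig(), seed=11)


def random_discrete(
    rng: np.random.Generator,
    ntax: int,
    nchar: int,
    n_states: int = 3,
    missing_frac: float = 0.3,
    poly_frac: float = 0.05,
) -> DiscreteMatrix:
    taxa = [f"t{i}" for i in range(ntax)]
    states = []
    for _ in range(ntax):
        row = []
        for _ in range(nchar):
            u = rng.random()
            if u < missing_frac:
                row.append(None)
            elif u < missing_frac + poly_frac:
                a = int(rng.integers(n_states))
                b = (a + 1 + int(rng.integers(n_states - 1))) % n_states
                row.append(frozenset({a, b}))
            else:
                row.append(frozenset({int(rng.integers(n_states))}))
        states.append(row)
    return DiscreteMatrix(taxa=taxa, states=states)
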