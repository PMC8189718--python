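"""Shared fixtures: seeded random graphs, ensembles, and landscapes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from allokit.graphcore import (
    EquilibriumGraph,
    LabeledDigraph,
    labels_from_free_energies,
)
from allokit.homeasures import FreeEnergyLandscape
from allokit.interface import FixtureSpec, random_ensemble


def random_equilibrium_graph(
    n_vertices: int, extra_edges: int, seed: int
) -> EquilibriumGraph:
    """Random connected equilibrium-consistent graph via vertex energies.

    A random spanning tree plus ``extra_edges`` chords, labelled from
    random free energies so the cycle condition holds exactly.
    """
    rng = np.random.default_rng(seed)
    vertices = list(range(1, n_vertices + 1))
    energies = {v: float(rng.normal(scale=2.0)) for v in vertices}
    edges = set()
    for v in vertices[1:]:
        u = int(rng.integers(1, v))
        edges.add((u, v))
    while len(edges) < n_vertices - 1 + extra_edges:
        u, v = rng.choice(vertices, size=2, replace=False)
        u, v = int(u), int(v)
        if u != v and (u, v) not in edges and (v, u) not in edges:
            edges.add((u, v))
    return labels_from_free_energies(energies, edges, reference=1)


def random_rate_graph(eg: EquilibriumGraph, seed: int) -> LabeledDigraph:
    """A rate graph realizing ``eg`` with random forward/reverse splits."""
    rng = np.random.default_rng(seed)
    labels = {}
    for (i, j), ll in eg.log_labels.items():
        if (j, i) in labels:
            continue
        rev = float(rng.uniform(0.2, 5.0))
        labels[(i, j)] = rev * math.exp(ll)
        labels[(j, i)] = rev
    return LabeledDigraph(vertices=list(eg.vertices), labels=labels)


def random_landscape(n: int, seed: int) -> FreeEnergyLandscape:
    from allokit.allostery import subsets

    rng = np.random.default_rng(seed)
    return FreeEnergyLandscape(
        n=n, DeltaPhi={S: float(rng.normal(scale=1.5)) for S in subsets(n)}
    )


@pytest.fixture
def small_ensemble():
    """A 2-site, 3-conformation ensemble with intrinsic cooperativities."""
    return random_ensemble(FixtureSpec(n=2, N=3, seed=42, omega_mode="random"))


@pytest.fixture
def mwc_ensemble():
    """Independent identical sites: 4 sites, 2 conformations (classical MWC)."""
    from allokit.allostery import AllosteryGraph, ConformationTable, HorizontalSpec

    K_R, K_T, L = 2.0, 15.0, 40.0
    confs = ["R", "T"]
    table = ConformationTable(
        n=4,
        conformations=confs,
        log_K_bare={(c, i): math.log(K) for c, K in zip(confs, (K_R, K_T)) for i in range(1, 5)},
    )
    horiz = HorizontalSpec(conformations=confs, log_lambda={"R": 0.0, "T": math.log(L)})
    return AllosteryGraph(n=4, table=table, horiz=horiz), (K_R, K_T, L)
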