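"""Reversible labelled digraphs and equilibrium steady states.

A finite-state continuous-time Markov process is represented as a labelled
digraph: vertices are states, directed edges are transitions, and each edge
carries a positive rate. The graph Laplacian generates the master equation,
and its one-dimensional kernel (for a strongly connected graph) is the
steady state. At thermodynamic equilibrium the description simplifies: only
the ratios of forward to reverse rates matter, and these *equilibrium
labels* satisfy the cycle condition — the product of labels around any
cycle is 1. The steady state is then given by path products of equilibrium
labels from a reference vertex (detailed balance).

All path-product and partition-function arithmetic is carried out in the
log domain: downstream constructions routinely produce labels spanning many
tens of orders of magnitude, which overflow naive products.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Tuple

import networkx as nx
import numpy as np
from scipy.special import logsumexp

Vertex = Hashable
Edge = Tuple[Vertex, Vertex]

__all__ = [
    "LabeledDigraph",
    "EquilibriumGraph",
    "SteadyState",
    "ReversibilityError",
    "EquilibriumError",
    "ConnectivityError",
    "from_rates",
    "check_cycle_condition",
    "mu",
    "log_mu",
    "steady_state",
    "laplacian_steady_state",
    "labels_from_free_energies",
    "spanning_tree",
]

#: default tolerance, in log units per cycle edge, for the cycle condition
DEFAULT_CYCLE_TOL = 1e-9


class ReversibilityError(ValueError):
    """An edge is missing its reverse companion."""


class EquilibriumError(ValueError):
    """The cycle condition fails beyond tolerance."""


class ConnectivityError(ValueError):
    """The graph is not (strongly) connected where it must be."""


@dataclass
class LabeledDigraph:
    """Directed graph with positive rate labels (units time^-1).

    Parameters
    ----------
    vertices
        Finite vertex set; order fixes determinism of traversals.
    labels
        Map ``(i, j) -> rate`` for each directed edge ``i -> j``.
        Self-loops are not allowed.
    """

    vertices: List[Vertex]
    labels: Dict[Edge, float]

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise ValueError("duplicate vertices")
        for (i, j), rate in self.labels.items():
            if i == j:
                raise ValueError(f"self-loop at {i!r}")
            if i not in vset or j not in vset:
                raise ValueError(f"edge ({i!r}, {j!r}) uses unknown vertex")
            if not rate > 0:
                raise ValueError(f"non-positive rate on ({i!r}, {j!r}): {rate}")

    def is_reversible(self) -> bool:
        return all((j, i) in self.labels for (i, j) in self.labels)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (i, j), rate in self.labels.items():
            g.add_edge(i, j, rate=rate)
        return g


@dataclass
class EquilibriumGraph:
    """Reversible graph parameterised by dimensionless equilibrium labels.

    Labels are stored in the log domain as ``log_labels[(i, j)]`` with the
    exact antisymmetry ``log_labels[(j, i)] == -log_labels[(i, j)]``. Only
    one orientation needs to be supplied; the reverse is filled in.
    """

    vertices: List[Vertex]
    log_labels: Dict[Edge, float]
    reference: Vertex = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reference is None:
            self.reference = self.vertices[0]
        if self.reference not in set(self.vertices):
            raise ValueError("reference vertex not in graph")
        # symmetrise: every edge gets its reverse with negated log label
        for (i, j), ll in list(self.log_labels.items()):
            if i == j:
                raise ValueError(f"self-loop at {i!r}")
            rev = self.log_labels.get((j, i))
            if rev is None:
                self.log_labels[(j, i)] = -ll
            elif rev != -ll:
                raise ReversibilityError(
                    f"labels on ({i!r},{j!r}) and reverse are not reciprocal"
                )
        und = self.undirected()
        if und.number_of_nodes() and not nx.is_connected(und):
            raise ConnectivityError("equilibrium graph must be connected")

    def label(self, i: Vertex, j: Vertex) -> float:
        return math.exp(self.log_labels[(i, j)])

    def edges(self) -> Iterable[Edge]:
        return self.log_labels.keys()

    def neighbors(self, v: Vertex) -> List[Vertex]:
        return sorted(
            (j for (i, j) in self.log_labels if i == v), key=self._vkey
        )

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from((i, j) for (i, j) in self.log_labels)
        return g

    def _vkey(self, v: Vertex):
        # lexicographic on repr keeps mixed vertex types orderable
        return (str(type(v)), repr(v))


@dataclass
class SteadyState:
    """Equilibrium steady state of an :class:`EquilibriumGraph`.

    ``log_mu`` holds the log path products relative to the reference vertex
    (``log_mu[reference] == 0``); ``probabilities`` are the normalised
    Boltzmann-like weights and ``log_partition`` is ``log(sum(mu))``.
    """

    log_mu: Dict[Vertex, float]
    probabilities: Dict[Vertex, float]
    log_partition: float

    @property
    def mu(self) -> Dict[Vertex, float]:
        return {v: math.exp(lm) for v, lm in self.log_mu.items()}

    @property
    def partition_value(self) -> float:
        return math.exp(self.log_partition)


def from_rates(g: LabeledDigraph, reference: Vertex | None = None) -> EquilibriumGraph:
    """Equilibrium graph of label ratios ``l(i->j)/l(j->i)``."""
    if not g.is_reversible():
        missing = [(i, j) for (i, j) in g.labels if (j, i) not in g.labels]
        raise ReversibilityError(f"missing reverse edges: {missing[:5]}")
    log_labels: Dict[Edge, float] = {}
    for (i, j), rate in g.labels.items():
        if (j, i) in log_labels:
            continue
        ll = math.log(rate) - math.log(g.labels[(j, i)])
        log_labels[(i, j)] = ll
        log_labels[(j, i)] = -ll
    return EquilibriumGraph(
        vertices=list(g.vertices),
        log_labels=log_labels,
        reference=reference if reference is not None else g.vertices[0],
    )


def spanning_tree(eg: EquilibriumGraph) -> List[Edge]:
    """Deterministic BFS spanning tree rooted at the reference vertex.

    Edges are oriented away from the root; neighbors are visited in
    lexicographic order, so the result depends only on the graph.
    """
    root = eg.reference
    seen = {root}
    tree: List[Edge] = []
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in eg.neighbors(u):
            if v not in seen:
                seen.add(v)
                tree.append((u, v))
                queue.append(v)
    if len(seen) != len(eg.vertices):
        raise ConnectivityError("graph is not connected")
    return tree


def _tree_log_mu(eg: EquilibriumGraph) -> Dict[Vertex, float]:
    """Log path products along the BFS spanning tree from the reference."""
    out = {eg.reference: 0.0}
    for (u, v) in spanning_tree(eg):
        out[v] = out[u] + eg.log_labels[(u, v)]
    return out


def check_cycle_condition(
    eg: EquilibriumGraph, tol: float = DEFAULT_CYCLE_TOL
) -> Tuple[bool, float]:
    """Check that label products around independent cycles are all 1.

    Each non-tree edge closes one independent cycle against the BFS
    spanning tree; its log-label sum must vanish. Returns ``(ok, worst)``
    where ``worst`` is the largest absolute cycle residual in log units.
    The tolerance is interpreted per cycle edge (longer cycles accumulate
    more rounding).
    """
    lmu = _tree_log_mu(eg)
    tree = set(spanning_tree(eg))
    tree |= {(v, u) for (u, v) in tree}
    worst = 0.0
    ok = True
    for (i, j), ll in eg.log_labels.items():
        if (i, j) in tree:
            continue
        residual = lmu[i] + ll - lmu[j]
        worst = max(worst, abs(residual))
        # cycle length <= tree-path length + 1; bound with vertex count
        if abs(residual) > tol * max(2, len(eg.vertices)):
            ok = False
    return ok, worst


def log_mu(eg: EquilibriumGraph, tol: float = DEFAULT_CYCLE_TOL) -> Dict[Vertex, float]:
    """Log of the path products mu(v) from the reference vertex.

    Raises :class:`EquilibriumError` if the cycle condition fails, since mu
    is only path-independent (well defined) at equilibrium.
    """
    ok, worst = check_cycle_condition(eg, tol)
    if not ok:
        raise EquilibriumError(
            f"cycle condition violated (worst log residual {worst:.3g})"
        )
    return _tree_log_mu(eg)


def mu(eg: EquilibriumGraph, v: Vertex, tol: float = DEFAULT_CYCLE_TOL) -> float:
    """Path product of equilibrium labels from the reference vertex to v."""
    return math.exp(log_mu(eg, tol)[v])


def steady_state(eg: EquilibriumGraph, tol: float = DEFAULT_CYCLE_TOL) -> SteadyState:
    """Equilibrium probabilities Pr(v) = mu(v) / sum(mu)."""
    lmu = log_mu(eg, tol)
    order = list(eg.vertices)
    arr = np.array([lmu[v] for v in order])
    logZ = float(logsumexp(arr))
    probs = np.exp(arr - logZ)
    return SteadyState(
        log_mu=lmu,
        probabilities={v: float(p) for v, p in zip(order, probs)},
        log_partition=logZ,
    )


def laplacian_steady_state(g: LabeledDigraph) -> Dict[Vertex, float]:
    """Steady state from the kernel of the graph Laplacian (oracle route).

    Works for any strongly connected labelled digraph, equilibrium or not,
    so it serves as an independent check on the path-product calculation.
    """
    gx = g.to_networkx()
    if not nx.is_strongly_connected(gx):
        raise ConnectivityError("Laplacian steady state needs strong connectivity")
    order = list(g.vertices)
    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    L = np.zeros((n, n))
    for (i, j), rate in g.labels.items():
        L[idx[j], idx[i]] += rate
        L[idx[i], idx[i]] -= rate
    # replace one balance equation by normalisation; strong connectivity
    # guarantees a unique solution
    A = np.vstack([L[:-1, :], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(sol < -1e-9):
        raise ConnectivityError("Laplacian kernel is not a probability vector")
    sol = np.clip(sol, 0.0, None)
    sol /= sol.sum()
    return {v: float(sol[idx[v]]) for v in order}


def labels_from_free_energies(
    vertex_energies: Mapping[Vertex, float],
    edges: Iterable[Edge],
    reference: Vertex | None = None,
) -> EquilibriumGraph:
    """Equilibrium graph from dimensionless vertex free energies.

    ``l_eq(i -> j) = exp(-(Phi_j - Phi_i))`` with energies in kBT units, so
    the cycle condition holds exactly by construction and steady-state
    probabilities are Boltzmann weights.
    """
    vertices = list(vertex_energies)
    log_labels: Dict[Edge, float] = {}
    for (i, j) in edges:
        if (i, j) in log_labels:
            continue
        ll = -(vertex_energies[j] - vertex_energies[i])
        log_labels[(i, j)] = ll
        log_labels[(j, i)] = -ll
    return EquilibriumGraph(
        vertices=vertices,
        log_labels=log_labels,
        reference=reference if reference is not None else vertices[0],
    )


def rate_realization(eg: EquilibriumGraph) -> LabeledDigraph:
    """A rate graph whose label ratios reproduce ``eg``.

    Any split of each equilibrium label into forward/reverse rates is valid
    at equilibrium; the canonical choice here is forward = label,
    reverse = 1.
    """
    labels: Dict[Edge, float] = {}
    for (i, j), ll in eg.log_labels.items():
        if (j, i) in labels:
            continue
        labels[(i, j)] = math.exp(ll)
        labels[(j, i)] = 1.0
    return LabeledDigraph(vertices=list(eg.vertices), labels=labels)
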