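"""Coarse graining and effective higher-order cooperativities.

Partitioning the vertices of an equilibrium graph into blocks and summing
steady-state weights yields a quotient graph that is again at equilibrium,
with block probabilities equal to the summed fine-grained probabilities.
Applied to an allostery graph partitioned by its horizontal layers, the
quotient is a single effective binding hypercube whose labels define
*effective* association constants ``Kphi[i,S]`` and effective HOCs
``omegaphi[i,S] = Kphi[i,S] / Kphi[i,empty]``.

Both routes to the effective parameters are implemented: the closed-form
conformational averages (the primary route) and explicit coarse graining of
the built graph; their agreement is a structural check of the theory and is
exercised in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Hashable, List, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .allostery import EMPTY, AllosteryGraph, Subset, mask_subset, subsets
from .graphcore import ConnectivityError, EquilibriumGraph, Vertex, log_mu

__all__ = [
    "Partition",
    "EffectiveParams",
    "coarse_grain",
    "effective_params",
    "effective_assoc",
    "effective_hoc",
    "mwc_like_hoc",
    "negative_coop_sign",
]


@dataclass
class Partition:
    """Disjoint vertex blocks covering the whole graph."""

    blocks: Dict[Hashable, List[Vertex]]

    def __post_init__(self) -> None:
        seen: set = set()
        for name, block in self.blocks.items():
            if not block:
                raise ValueError(f"empty block {name!r}")
            overlap = seen.intersection(block)
            if overlap:
                raise ValueError(f"blocks overlap on {sorted(map(repr, overlap))[:3]}")
            seen.update(block)

    def block_of(self) -> Dict[Vertex, Hashable]:
        return {v: name for name, block in self.blocks.items() for v in block}


def coarse_grain(eg: EquilibriumGraph, p: Partition) -> EquilibriumGraph:
    """Quotient equilibrium graph of a partition.

    The quotient has an edge between two blocks iff the fine graph has one,
    and its equilibrium label is the ratio of summed path products:
    ``l(u -> v) = sum(mu, block v) / sum(mu, block u)``. At steady state the
    quotient block probabilities equal the summed fine probabilities.
    """
    owner = p.block_of()
    missing = set(eg.vertices) - owner.keys()
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} vertices")
    lmu = log_mu(eg)
    block_lmu = {
        name: float(logsumexp([lmu[v] for v in block]))
        for name, block in p.blocks.items()
    }
    names = list(p.blocks)
    quotient_edges = set()
    for (i, j) in eg.edges():
        u, v = owner[i], owner[j]
        if u != v:
            quotient_edges.add((u, v))
    log_labels = {
        (u, v): block_lmu[v] - block_lmu[u] for (u, v) in quotient_edges
    }
    und = nx.Graph(list(quotient_edges))
    und.add_nodes_from(names)
    if len(names) > 1 and not nx.is_connected(und):
        raise ConnectivityError("partition induces a disconnected quotient")
    return EquilibriumGraph(
        vertices=names,
        log_labels=log_labels,
        reference=owner[eg.reference],
    )


@dataclass
class EffectiveParams:
    """Effective association constants of the coarse-grained ensemble.

    ``log_Kphi[(i, S)]`` holds ``log Kphi[i, S]`` for every site i and
    context S with ``i not in S``. Effective HOCs are the ratios to the
    empty context and are independent of ligand concentration.
    """

    n: int
    log_Kphi: Dict[Tuple[int, Subset], float]

    def Kphi(self, i: int, S: Subset = EMPTY) -> float:
        return math.exp(self.log_Kphi[(i, frozenset(S))])

    def omegaphi(self, i: int, S: Subset) -> float:
        S = frozenset(S)
        return math.exp(self.log_Kphi[(i, S)] - self.log_Kphi[(i, EMPTY)])

    def is_independent(self, i: int, S: Subset) -> bool:
        """Whether (i, S) is in the independent reporting set i < S."""
        return all(i < j for j in S)

    def log_mu_phi(self, S: Subset) -> float:
        """Log path product mu_S of the effective hypercube at x = 1.

        Ordered product of effective constants binding the highest site
        first, so each factor uses a context above the bound site.
        """
        sites = sorted(S)
        return sum(
            self.log_Kphi[(i, frozenset(sites[k + 1:]))]
            for k, i in enumerate(sites)
        )

    def rows(self) -> List[Dict[str, object]]:
        """Tabular listing (one row per (i, S) pair, i not in S)."""
        out = []
        for S in subsets(self.n):
            for i in range(1, self.n + 1):
                if i in S:
                    continue
                out.append(
                    {
                        "i": i,
                        "S": sorted(S),
                        "K_phi": self.Kphi(i, S),
                        "omega_phi": self.omegaphi(i, S),
                        "independent": self.is_independent(i, S),
                    }
                )
        return out


def effective_params(A: AllosteryGraph) -> EffectiveParams:
    """Effective parameters by lambda-weighted conformational averages.

    ``Kphi[i,S]`` is the average of ``K[c,i,S]`` over conformations,
    weighted by the equilibrium probability of conformation c in the
    horizontal layer of context S — i.e. weights proportional to
    ``lambda_c * mu_S(c)``. Evaluated wholly in the log domain.
    """
    table, horiz = A.table, A.horiz
    confs = A.conformations
    log_lam = np.array([horiz.log_lambda[c] for c in confs])
    log_Kphi: Dict[Tuple[int, Subset], float] = {}
    for S in subsets(A.n):
        log_w = log_lam + np.array(
            [table.log_mu_vertical(c, S) for c in confs]
        )
        log_den = logsumexp(log_w)
        for i in range(1, A.n + 1):
            if i in S:
                continue
            log_Ki = np.array([table.log_assoc(c, i, S) for c in confs])
            log_Kphi[(i, S)] = float(logsumexp(log_w + log_Ki) - log_den)
    return EffectiveParams(n=A.n, log_Kphi=log_Kphi)


def effective_assoc(A: AllosteryGraph) -> Dict[Tuple[int, Subset], float]:
    """Effective association constants Kphi[i, S] as plain floats."""
    eff = effective_params(A)
    return {k: math.exp(v) for k, v in eff.log_Kphi.items()}


def effective_hoc(A: AllosteryGraph) -> Dict[Tuple[int, Subset], float]:
    """Effective HOCs omegaphi[i, S] (equal to 1 for S = empty)."""
    eff = effective_params(A)
    return {
        (i, S): eff.omegaphi(i, S) for (i, S) in eff.log_Kphi
    }


def mwc_like_hoc(K: Sequence[float], probs: Sequence[float], s: int) -> float:
    """Effective HOC of order s for independent identical sites.

    For an MWC-like ensemble the effective HOC depends only on the number
    of sites already bound and reduces to a ratio of moments of the
    per-conformation constant K over the conformational distribution:
    ``omega_s = <K**(s+1)> / (<K> * <K**s>)``.
    """
    K = np.asarray(K, dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any(K <= 0) or np.any(p < 0):
        raise ValueError("constants must be positive and probabilities non-negative")
    p = p / p.sum()
    m = lambda k: float(np.sum(p * K**k))
    return m(s + 1) / (m(1) * m(s))


def negative_coop_sign(
    K_c1: Tuple[float, float], K_c2: Tuple[float, float]
) -> int:
    """Sign of the effective pairwise cooperativity minus one.

    For two conformations with two independent sites the effective
    cooperativity is below 1 — negative cooperativity — exactly when the
    sites have opposite patterns of association constants across the
    conformations, for every horizontal parameter:
    ``omegaphi < 1  iff  (K11 - K21) * (K12 - K22) < 0``.
    """
    d = float(K_c1[0] - K_c2[0]) * float(K_c1[1] - K_c2[1])
    return (d > 0) - (d < 0)
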