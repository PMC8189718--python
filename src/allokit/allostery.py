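"""Product-structured allostery graphs.

An allosteric conformational ensemble with ``N`` conformations and ``n``
ligand-binding sites is a graph on ``N * 2**n`` vertices ``(c, S)``:
conformation ``c`` with the sites in subset ``S`` occupied. "Vertical"
edges bind/unbind ligand within a conformation with labels ``x * K[c,i,S]``
(``x`` the ligand concentration, ``K`` the association constant);
"horizontal" edges interchange conformations. Detailed balance pins every
horizontal label to those of a single horizontal layer, conventionally the
empty-binding layer, whose path products ``lambda_c`` are free parameters.

Association constants within a conformation are parameterised by the bare
constants ``K[c,i,empty]`` and the intrinsic higher-order cooperativities
(HOCs) ``omega[c,i,S]`` for ``i < S`` (``i`` below every site of ``S``),
which form a complete independent set; all other constants follow from the
cycle condition and are derived, never stored.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np

from .graphcore import EquilibriumGraph

Subset = FrozenSet[int]
EMPTY: Subset = frozenset()

__all__ = [
    "EMPTY",
    "subsets",
    "subset_mask",
    "mask_subset",
    "ConformationTable",
    "HorizontalSpec",
    "AllosteryGraph",
    "build",
]


def subsets(n: int, size: int | None = None) -> List[Subset]:
    """All subsets of sites {1..n}, in ascending-bitmask order."""
    out = []
    for mask in range(2**n):
        S = frozenset(i for i in range(1, n + 1) if mask >> (i - 1) & 1)
        if size is None or len(S) == size:
            out.append(S)
    return out


def subset_mask(S: Iterable[int]) -> int:
    """Bitmask of a site subset (site 1 = lowest bit)."""
    return sum(1 << (i - 1) for i in S)


def mask_subset(mask: int) -> Subset:
    return frozenset(i + 1 for i in range(mask.bit_length()) if mask >> i & 1)


def _precedes(i: int, S: Subset) -> bool:
    """The ordering convention i < S: i strictly below every site of S."""
    return all(i < j for j in S)


@dataclass
class ConformationTable:
    """Independent binding parameters for every conformation.

    Parameters
    ----------
    n
        Number of binding sites.
    conformations
        Conformation identifiers, reference first.
    log_K_bare
        ``(c, i) -> log K[c, i, empty]`` for every conformation and site.
    log_omega
        ``(c, i, S) -> log omega[c, i, S]`` for ``i < S`` only; missing
        entries default to 0 (no intrinsic cooperativity).
    """

    n: int
    conformations: List[str]
    log_K_bare: Dict[Tuple[str, int], float]
    log_omega: Dict[Tuple[str, int, Subset], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.conformations:
            for i in range(1, self.n + 1):
                if (c, i) not in self.log_K_bare:
                    raise ValueError(f"missing bare constant for ({c!r}, site {i})")
        for (c, i, S) in self.log_omega:
            if not _precedes(i, S) or not S:
                raise ValueError(
                    f"intrinsic HOC key ({c!r},{i},{set(S)}) must satisfy i < S"
                )

    def log_mu_vertical(self, c: str, S: Subset) -> float:
        """Log of mu_S for the vertical subgraph of ``c`` at x = 1.

        Binds the sites of S along the canonical path through the
        independent parameters: highest site first, so every step binds
        site ``i`` in a context lying strictly above it.
        """
        sites = sorted(S)
        total = 0.0
        for k, i in enumerate(sites):
            ctx = frozenset(sites[k + 1:])
            total += self.log_K_bare[(c, i)] + self.log_omega.get((c, i, ctx), 0.0)
        return total

    def log_assoc(self, c: str, i: int, S: Subset) -> float:
        """Log association constant K[c, i, S] for arbitrary ``i not in S``.

        Defined as ``mu(S + {i}) / mu(S)``; path independence is automatic
        because both path products come from the same independent set.
        """
        if i in S:
            raise ValueError(f"site {i} already bound in {set(S)}")
        return self.log_mu_vertical(c, S | {i}) - self.log_mu_vertical(c, S)

    def assoc_constant(self, c: str, i: int, S: Subset) -> float:
        return math.exp(self.log_assoc(c, i, S))

    def intrinsic_hoc(self, c: str, i: int, S: Subset) -> float:
        """omega[c, i, S] = K[c, i, S] / K[c, i, empty] for any i not in S."""
        return math.exp(self.log_assoc(c, i, S) - self.log_K_bare[(c, i)])


@dataclass
class HorizontalSpec:
    """Equilibrium path products of the empty-binding horizontal layer.

    ``log_lambda[c]`` is the log path product from the reference
    conformation to ``c`` within the empty layer (reference exactly 0).
    """

    conformations: List[str]
    log_lambda: Dict[str, float]

    def __post_init__(self) -> None:
        ref = self.conformations[0]
        if self.log_lambda.get(ref, 0.0) != 0.0:
            raise ValueError("reference conformation must have lambda = 1")
        self.log_lambda.setdefault(ref, 0.0)
        for c in self.conformations:
            if c not in self.log_lambda:
                raise ValueError(f"missing lambda for conformation {c!r}")


@dataclass
class AllosteryGraph:
    """An allosteric ensemble: binding table plus horizontal parameters."""

    n: int
    table: ConformationTable
    horiz: HorizontalSpec

    def __post_init__(self) -> None:
        if self.table.conformations != self.horiz.conformations:
            raise ValueError("table and horizontal spec disagree on conformations")
        if self.table.n != self.n:
            raise ValueError("table has wrong number of sites")

    @property
    def conformations(self) -> List[str]:
        return self.table.conformations

    @property
    def N(self) -> int:
        return len(self.conformations)

    def independent_params(self, free_only: bool = False) -> Dict[str, object]:
        """The complete independent parameter set of the ensemble.

        Per conformation: the n bare constants plus one intrinsic HOC for
        each (i, S) with i < S and S non-empty — ``2**n - 1`` vertical
        parameters in all — plus ``N - 1`` horizontal labels. With
        ``free_only`` the intrinsic HOCs structurally fixed at 1 (absent
        from the table) are omitted, leaving only the freely varying
        parameters (e.g. 24 + 3 = 27 for a 4-conformation, 6-site ensemble
        with no intrinsic cooperativity).
        """
        vertical = []
        for c in self.conformations:
            for i in range(1, self.n + 1):
                vertical.append(("K", c, i, EMPTY))
            for S in subsets(self.n):
                if not S:
                    continue
                for i in range(1, min(S)):
                    if free_only and (c, i, S) not in self.table.log_omega:
                        continue
                    vertical.append(("omega", c, i, S))
        horizontal = [("lambda", c) for c in self.conformations[1:]]
        return {
            "vertical": vertical,
            "horizontal": horizontal,
            "count": len(vertical) + len(horizontal),
        }


def build(
    A: AllosteryGraph,
    x: float,
    horizontal: str = "star",
) -> EquilibriumGraph:
    """Explicit equilibrium graph of the ensemble at ligand concentration x.

    Vertices are ``(c, mask)`` pairs. Vertical labels are ``x * K[c,i,S]``.
    Horizontal labels follow from detailed balance: the label from
    ``(c_ref, S)`` to ``(c, S)`` is ``lambda_c * mu_S(c) / mu_S(c_ref)``.
    Only the connectivity of the horizontal layers is a free choice
    (``"star"``, ``"path"`` or ``"complete"``); at equilibrium the steady
    state is independent of it.
    """
    if x <= 0:
        raise ValueError("ligand concentration must be positive to build the graph")
    n, table, horiz = A.n, A.table, A.horiz
    confs = A.conformations
    logx = math.log(x)
    vertices = [(c, mask) for c in confs for mask in range(2**n)]
    log_labels: Dict[Tuple[Tuple[str, int], Tuple[str, int]], float] = {}

    # vertical binding edges
    for c in confs:
        for mask in range(2**n):
            S = mask_subset(mask)
            for i in range(1, n + 1):
                if i in S:
                    continue
                ll = logx + table.log_assoc(c, i, S)
                log_labels[((c, mask), (c, mask | 1 << (i - 1)))] = ll
                log_labels[((c, mask | 1 << (i - 1)), (c, mask))] = -ll

    # horizontal conformational edges, per layer
    def add_h(c1: str, c2: str, mask: int) -> None:
        S = mask_subset(mask)
        ll = (
            horiz.log_lambda[c2]
            - horiz.log_lambda[c1]
            + table.log_mu_vertical(c2, S)
            - table.log_mu_vertical(c1, S)
        )
        log_labels[((c1, mask), (c2, mask))] = ll
        log_labels[((c2, mask), (c1, mask))] = -ll

    if horizontal == "star":
        pairs = [(confs[0], c) for c in confs[1:]]
    elif horizontal == "path":
        pairs = list(zip(confs[:-1], confs[1:]))
    elif horizontal == "complete":
        pairs = list(itertools.combinations(confs, 2))
    else:
        raise ValueError(f"unknown horizontal realization {horizontal!r}")
    for mask in range(2**n):
        for c1, c2 in pairs:
            add_h(c1, c2, mask)

    return EquilibriumGraph(
        vertices=vertices,
        log_labels=log_labels,
        reference=(confs[0], 0),
    )
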