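"""Interconversion of higher-order measures on the binding hypercube.

Three equivalent languages describe synergy among n sites of a free-energy
landscape ``Phi_S`` (one dimensionless free energy per subset of bound or
perturbed sites, in kBT units, with no zero-point convention imposed):

* **HOCs** ``omega[i,S]``: fold-changes of association constants, attached
  to hypercube edges.
* **Residual free energies** ``phi_S``: what remains of ``Phi_S`` after
  subtracting the contributions of every proper subset — attached to
  vertices, the collective synergy of S.
* **Higher-order couplings** ``Delta^k gamma``: iterated mutant-cycle
  differences over an ordered perturbation sequence around an offset
  subset; at offset empty they coincide with residual free energies and
  are invariant under permutation of the sequence.

Order is counted differently between the languages: the k = 2 coupling at
empty offset corresponds to the order-1 (pairwise) HOC. Both indexings are
exposed as-is rather than reconciled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Sequence, Tuple

from .allostery import EMPTY, Subset, subsets

__all__ = [
    "FreeEnergyLandscape",
    "ResidualEnergies",
    "CouplingSpec",
    "hoc_from_landscape",
    "hoc_table",
    "residual_energies",
    "residual_from_hoc",
    "coupling",
    "coupling_from_hoc",
]


@dataclass
class FreeEnergyLandscape:
    """Dimensionless free energy for every one of the 2**n subsets."""

    n: int
    DeltaPhi: Dict[Subset, float]

    def __post_init__(self) -> None:
        expected = set(subsets(self.n))
        self.DeltaPhi = {frozenset(S): float(v) for S, v in self.DeltaPhi.items()}
        if set(self.DeltaPhi) != expected:
            raise ValueError("landscape must assign an energy to every subset")
        for v in self.DeltaPhi.values():
            if not math.isfinite(v):
                raise ValueError("energies must be finite")


@dataclass
class ResidualEnergies:
    """Residual free energies phi_S; reconstruction of Phi is exact."""

    n: int
    DeltaPhiRes: Dict[Subset, float]

    def reconstruct(self) -> Dict[Subset, float]:
        """Phi_S = sum of residuals over all subsets of S."""
        return {
            S: sum(v for X, v in self.DeltaPhiRes.items() if X <= S)
            for S in subsets(self.n)
        }


@dataclass(frozen=True)
class CouplingSpec:
    """Offset subset Z plus an ordered disjoint perturbation sequence."""

    offset: Subset
    sequence: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", frozenset(self.offset))
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("perturbation sequence has repeated sites")
        if self.offset & set(self.sequence):
            raise ValueError("offset and sequence must be disjoint")

    @property
    def k(self) -> int:
        return len(self.sequence)


def hoc_from_landscape(L: FreeEnergyLandscape, i: int, S: Subset) -> float:
    """HOC from free energies.

    ``omega[i,S] = exp(-[(Phi_{S+i} - Phi_S) - (Phi_{i} - Phi_empty)])`` —
    the Boltzmann factor of the extra cost (or gain) of binding i in
    context S relative to binding it first.
    """
    S = frozenset(S)
    if i in S:
        raise ValueError(f"site {i} is already in the context")
    P = L.DeltaPhi
    return math.exp(
        -((P[S | {i}] - P[S]) - (P[frozenset({i})] - P[EMPTY]))
    )


def hoc_table(L: FreeEnergyLandscape) -> Dict[Tuple[int, Subset], float]:
    """omega[i, S] for every site i and context S with i not in S."""
    out = {}
    for S in subsets(L.n):
        for i in range(1, L.n + 1):
            if i not in S:
                out[(i, S)] = hoc_from_landscape(L, i, S)
    return out


def residual_energies(L: FreeEnergyLandscape, route: str = "recursion") -> ResidualEnergies:
    """Residual free energies, by recursion or by inclusion-exclusion.

    The recursive route peels proper-subset contributions off one subset
    at a time; the direct route is the signed Moebius sum
    ``phi_S = sum_{Y <= S} (-1)**(|S|-|Y|) Phi_Y``. The two agree exactly
    (up to float associativity) and both are kept as mutual checks.
    """
    P = L.DeltaPhi
    res: Dict[Subset, float] = {}
    if route == "recursion":
        for S in sorted(subsets(L.n), key=len):
            res[S] = P[S] - sum(res[X] for X in subsets(L.n) if X < S)
    elif route == "inclusion-exclusion":
        for S in subsets(L.n):
            res[S] = sum(
                (-1) ** (len(S) - len(Y)) * P[Y]
                for Y in subsets(L.n)
                if Y <= S
            )
    else:
        raise ValueError(f"unknown route {route!r}")
    return ResidualEnergies(n=L.n, DeltaPhiRes=res)


def residual_from_hoc(
    omega: Mapping[Tuple[int, Subset], float], S: Subset, i: int | None = None
) -> float:
    """exp(-phi_S) from HOCs, for subsets of two or more sites.

    ``exp(-phi_S) = prod over Z <= S - {i} of omega[i,Z] ** sign`` with
    sign ``(-1)**(|S|-|Z|-1)``; the anchor site i in S is arbitrary and the
    result does not depend on it. For singletons the ligand itself
    contributes and the residual is not expressible in HOCs alone.
    """
    S = frozenset(S)
    if len(S) <= 1:
        raise ValueError("residuals from HOCs need at least two sites")
    if i is None:
        i = min(S)
    if i not in S:
        raise ValueError("anchor site must belong to the subset")
    rest = sorted(S - {i})
    log_total = 0.0
    for r in range(len(rest) + 1):
        for Z in itertools.combinations(rest, r):
            sign = (-1) ** (len(S) - len(Z) - 1)
            log_total += sign * math.log(omega[(i, frozenset(Z))])
    return math.exp(log_total)


def coupling(L: FreeEnergyLandscape, spec: CouplingSpec) -> float:
    """k-th order coupling by the mutant-cycle recursion.

    First order is a plain difference across the offset; each further
    order differences the previous one between the perturbed and
    unperturbed value of the last site in the sequence. At k = 2, offset
    empty, this is the standard double-mutant-cycle coupling free energy.
    """
    Z, seq = spec.offset, spec.sequence
    if spec.k == 0:
        raise ValueError("coupling needs at least one perturbation")
    if spec.k == 1:
        return L.DeltaPhi[Z | {seq[0]}] - L.DeltaPhi[Z]
    head = CouplingSpec(offset=Z, sequence=seq[:-1])
    shifted = CouplingSpec(offset=Z | {seq[-1]}, sequence=seq[:-1])
    return coupling(L, shifted) - coupling(L, head)


def coupling_from_hoc(
    omega: Mapping[Tuple[int, Subset], float], spec: CouplingSpec
) -> float:
    """exp(-Delta^k gamma) from HOCs, for k >= 2.

    ``prod over X <= {i2..ik} of omega[i1, Z + X] ** ((-1)**(k-1-|X|))``.
    At k = 1 the ligand contribution enters and the coupling must be taken
    from the landscape route instead.
    """
    if spec.k < 2:
        raise ValueError("HOC route needs k >= 2 (order 1 involves the ligand)")
    i1, rest = spec.sequence[0], spec.sequence[1:]
    log_total = 0.0
    for r in range(len(rest) + 1):
        for X in itertools.combinations(rest, r):
            sign = (-1) ** (spec.k - 1 - len(X))
            log_total += sign * math.log(omega[(i1, spec.offset | frozenset(X))])
    return math.exp(log_total)
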