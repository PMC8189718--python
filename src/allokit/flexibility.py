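"""Constructive realization of arbitrary effective cooperativity patterns.

Any positive target pattern — bare effective association constants
``beta_i`` and effective HOCs ``alpha[i,S]`` for ``i < S``, ``2**n - 1``
numbers in all — can be realized to arbitrary accuracy by an ensemble with
**no intrinsic cooperativity in any conformation**. The construction uses
one conformation ``c_T`` per site subset T:

* bare constants ``K[c_T, i] = kappa_i`` if ``i in T`` else
  ``eps * kappa_i`` — site i binds well only in the conformations "tuned"
  to it;
* horizontal weights ``lambda_T = alpha[i1,{i2..ik}] * alpha[i2,{i3..ik}]
  * ... * alpha[i_{k-1},{ik}] * delta**k`` for ``T = {i1 < ... < ik}``;
* ``kappa_i = beta_i * sum(lambda) / sum(lambda over T containing i)``.

As ``eps, delta -> 0`` the effective parameters converge to the targets.
The limits are nested: at finite values the residual error scales like
``O(eps/delta) + O(delta)``, so ``eps`` must shrink faster than ``delta``
(the worked examples use eps between 1e-12 and 1e-16 with delta = 1e-7);
the deviation achieved is the max relative error reported by
:func:`verify`. The lambda weights span ``delta**n`` and the vertical
weights pick up powers of ``eps``, so everything is computed in the log
domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
from scipy.special import logsumexp

from .allostery import (
    EMPTY,
    AllosteryGraph,
    ConformationTable,
    HorizontalSpec,
    Subset,
    subsets,
)
from .effective import EffectiveParams, effective_params

__all__ = ["TargetPattern", "FlexEnsemble", "construct", "verify"]


@dataclass
class TargetPattern:
    """Target effective parameters: n betas and 2**n - n - 1 alphas."""

    n: int
    beta: Dict[int, float]
    alpha: Dict[Tuple[int, Subset], float]

    def __post_init__(self) -> None:
        if set(self.beta) != set(range(1, self.n + 1)):
            raise ValueError("beta must cover sites 1..n")
        self.alpha = {(i, frozenset(S)): v for (i, S), v in self.alpha.items()}
        expected = {
            (i, S)
            for S in subsets(self.n)
            if S
            for i in range(1, min(S))
        }
        if set(self.alpha) != expected:
            raise ValueError(
                "alpha must cover exactly the independent pairs (i, S) with i < S"
            )
        if any(v <= 0 for v in self.beta.values()) or any(
            v <= 0 for v in self.alpha.values()
        ):
            raise ValueError("targets must be positive")


def conf_id(T: Subset) -> str:
    return "c{" + ",".join(map(str, sorted(T))) + "}"


@dataclass
class FlexEnsemble:
    """The constructed ensemble plus its accuracy controls."""

    target: TargetPattern
    eps: float
    delta: float
    graph: AllosteryGraph
    log_kappa: Dict[int, float]
    log_lambda_T: Dict[Subset, float]

    @property
    def kappa(self) -> Dict[int, float]:
        return {i: math.exp(v) for i, v in self.log_kappa.items()}


def _log_lambdas(t: TargetPattern, delta: float) -> Dict[Subset, float]:
    """log lambda_T: nested alpha path-product times delta**|T|."""
    out: Dict[Subset, float] = {}
    for T in subsets(t.n):
        sites = sorted(T)
        ll = len(T) * math.log(delta) if T else 0.0
        for j in range(len(sites) - 1):
            ll += math.log(t.alpha[(sites[j], frozenset(sites[j + 1:]))])
        out[T] = ll
    return out


def construct(t: TargetPattern, eps: float, delta: float) -> FlexEnsemble:
    """Build the ensemble realizing the target pattern.

    ``eps`` suppresses binding in conformations not tuned to a site and
    ``delta`` separates the horizontal weight scales of differently sized
    T; both must lie in (0, 1), and smaller is more accurate.
    """
    if not (0 < eps < 1 and 0 < delta < 1):
        raise ValueError("eps and delta must lie in (0, 1)")
    log_lam = _log_lambdas(t, delta)
    Ts = subsets(t.n)
    all_lam = np.array([log_lam[T] for T in Ts])
    log_total = float(logsumexp(all_lam))
    log_kappa: Dict[int, float] = {}
    for i in range(1, t.n + 1):
        with_i = np.array([log_lam[T] for T in Ts if i in T])
        log_kappa[i] = math.log(t.beta[i]) + log_total - float(logsumexp(with_i))

    confs = [conf_id(T) for T in Ts]
    log_eps = math.log(eps)
    log_K_bare = {
        (conf_id(T), i): log_kappa[i] + (0.0 if i in T else log_eps)
        for T in Ts
        for i in range(1, t.n + 1)
    }
    table = ConformationTable(
        n=t.n, conformations=confs, log_K_bare=log_K_bare, log_omega={}
    )
    horiz = HorizontalSpec(
        conformations=confs,
        log_lambda={conf_id(T): log_lam[T] for T in Ts},
    )
    graph = AllosteryGraph(n=t.n, table=table, horiz=horiz)
    return FlexEnsemble(
        target=t,
        eps=eps,
        delta=delta,
        graph=graph,
        log_kappa=log_kappa,
        log_lambda_T=log_lam,
    )


@dataclass
class VerifyReport:
    """Per-target relative errors of the realized effective parameters."""

    Kphi: Dict[int, float]
    omegaphi: Dict[Tuple[int, Subset], float]
    beta_errors: Dict[int, float]
    alpha_errors: Dict[Tuple[int, Subset], float]
    max_error: float
    #: sensitivity of the residual error: max errors recomputed at eps/10
    #: and at delta/10 (the latter can worsen the eps/delta term, so these
    #: attribute the error rather than bound it)
    eps_limited: float | None = None
    delta_limited: float | None = None


def verify(
    t: TargetPattern, e: FlexEnsemble, attribute: bool = False
) -> VerifyReport:
    """Measure the realized effective parameters against the targets.

    Relative errors ``|beta - Kphi| / beta`` and ``|alpha - omegaphi| /
    alpha``; the max over all of them is the headline accuracy figure.
    With ``attribute=True`` the construction is re-run at ``eps/10`` and at
    ``delta/10`` to show which control limits the residual error.
    """
    eff = effective_params(e.graph)
    Kphi = {i: eff.Kphi(i, EMPTY) for i in range(1, t.n + 1)}
    omegaphi = {key: eff.omegaphi(*key) for key in t.alpha}
    beta_errors = {i: abs(t.beta[i] - Kphi[i]) / t.beta[i] for i in Kphi}
    alpha_errors = {
        key: abs(t.alpha[key] - omegaphi[key]) / t.alpha[key] for key in omegaphi
    }
    max_error = max(list(beta_errors.values()) + list(alpha_errors.values()))
    report = VerifyReport(
        Kphi=Kphi,
        omegaphi=omegaphi,
        beta_errors=beta_errors,
        alpha_errors=alpha_errors,
        max_error=max_error,
    )
    if attribute:
        report.eps_limited = verify(t, construct(t, e.eps / 10, e.delta)).max_error
        report.delta_limited = verify(t, construct(t, e.eps, e.delta / 10)).max_error
    return report
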