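"""Stochastic search for ensembles whose binding functions mimic Hill curves.

The search space is an ensemble of N conformations with n independent
binding sites each (no intrinsic cooperativity): N * n bare association
constants, restricted to ``[1e-4, 1e4]``, plus N - 1 horizontal labels
restricted to ``[1e-6, 1e6]``. Parameters are sampled and perturbed
logarithmically.

The procedure has two steps. **Screening** draws random parameter vectors
until the normalized binding function lands in a window of position/
steepness space near the Hill functions (``gamma in [0.5, 1.2]``, ``rho in
[0.5, 1.3]``). **Refinement** is a Monte Carlo loop: each parameter is
picked for perturbation with probability p and multiplied by a log-uniform
factor in [m, M] (clamped at the box); the move is accepted if the Hill
error delta decreases, and otherwise with a fixed probability beta — a
single Bernoulli draw, deliberately independent of the size of the error
increase. The proposal scale anneals as the error falls, via a configurable
piecewise schedule.

The single RNG stream is consumed in a fixed order per iteration —
proposal mask, then replacement values, then (only on a worsening move) the
acceptance draw — so runs are exactly reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .allostery import AllosteryGraph, ConformationTable, HorizontalSpec
from .binding import (
    BindingPolynomial,
    NormalizedCurve,
    ShapeMeasures,
    hill_error,
    normalize,
    shape,
)
from .effective import EffectiveParams, effective_params

__all__ = [
    "SearchSpace",
    "MCSettings",
    "SearchResult",
    "ScreeningError",
    "screen",
    "refine",
    "evaluate",
    "binding_polynomial",
]

K_BOUNDS = (1e-4, 1e4)
LAMBDA_BOUNDS = (1e-6, 1e6)

#: annealing stages: (apply while best delta >= threshold of next stage)
DEFAULT_SCHEDULE: Tuple[Tuple[float, float, float, float], ...] = (
    # (delta threshold, p, m, M): stage applies while best delta >= threshold
    (0.01, 0.5, 0.1, 10.0),
    (0.001, 0.2, 0.5, 2.0),
    (0.0, 0.05, 0.9, 1.1),
)


class ScreeningError(RuntimeError):
    """No draw passed the shape windows within the allowed budget."""


@dataclass
class SearchSpace:
    """Box-constrained parameter space of the no-intrinsic-HOC ensemble.

    The parameter vector is ``[K(c1,s1..sn), ..., K(cN,s1..sn),
    lambda_2..lambda_N]`` (conformation-major), handled internally in
    natural log.
    """

    n: int
    N: int
    k_bounds: Tuple[float, float] = K_BOUNDS
    lam_bounds: Tuple[float, float] = LAMBDA_BOUNDS

    @property
    def dim(self) -> int:
        return self.N * self.n + (self.N - 1)

    def log_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.dim)
        hi = np.empty(self.dim)
        nk = self.N * self.n
        lo[:nk], hi[:nk] = math.log(self.k_bounds[0]), math.log(self.k_bounds[1])
        lo[nk:], hi[nk:] = math.log(self.lam_bounds[0]), math.log(self.lam_bounds[1])
        return lo, hi

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One log-uniform draw from the box (natural-value vector)."""
        lo, hi = self.log_bounds()
        return np.exp(rng.uniform(lo, hi))

    def clamp(self, params: np.ndarray) -> np.ndarray:
        lo, hi = self.log_bounds()
        return np.exp(np.clip(np.log(params), lo, hi))

    def split(self, params: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        nk = self.N * self.n
        K = np.asarray(params[:nk], dtype=float).reshape(self.N, self.n)
        lam = np.concatenate([[1.0], np.asarray(params[nk:], dtype=float)])
        return K, lam

    def to_graph(self, params: np.ndarray) -> AllosteryGraph:
        K, lam = self.split(params)
        confs = [f"c{k + 1}" for k in range(self.N)]
        table = ConformationTable(
            n=self.n,
            conformations=confs,
            log_K_bare={
                (confs[k], i + 1): math.log(K[k, i])
                for k in range(self.N)
                for i in range(self.n)
            },
        )
        horiz = HorizontalSpec(
            conformations=confs,
            log_lambda={c: math.log(l) for c, l in zip(confs, lam)},
        )
        return AllosteryGraph(n=self.n, table=table, horiz=horiz)


def binding_polynomial(space: SearchSpace, params: np.ndarray) -> BindingPolynomial:
    """Partition polynomial of an independent-sites ensemble.

    With no intrinsic cooperativity the per-conformation partition function
    factorises as ``prod_i (1 + K[c,i] x)``; the ensemble polynomial is the
    lambda-weighted average of these, with exactly matching coefficients to
    the generic effective-parameter route.
    """
    K, lam = space.split(params)
    w = lam / lam.sum()
    coeffs = np.zeros(space.n + 1)
    for c in range(space.N):
        pc = np.ones(1)
        for i in range(space.n):
            pc = np.convolve(pc, [1.0, K[c, i]])
        coeffs += w[c] * pc
    log_coeffs = np.log(coeffs)
    log_coeffs[0] = 0.0  # exact by normalisation of the weights
    return BindingPolynomial(log_coeffs=log_coeffs)


def _delta(space: SearchSpace, params: np.ndarray, h: float) -> float:
    g = normalize(binding_polynomial(space, params))
    return hill_error(g, h)


@dataclass
class MCSettings:
    """Knobs of the refinement loop."""

    h: float
    beta: float = 0.5
    max_iter: int = 5_000_000
    tol: float = 2e-4
    seed: int = 0
    schedule: Tuple[Tuple[float, float, float, float], ...] = DEFAULT_SCHEDULE

    def stage(self, best_delta: float) -> Tuple[float, float, float]:
        """(p, m, M) applicable at the current best error."""
        for threshold, p, m, M in self.schedule:
            if best_delta >= threshold:
                return p, m, M
        return self.schedule[-1][1:]

    def __post_init__(self) -> None:
        if not 0 <= self.beta < 1:
            raise ValueError("beta must be in [0, 1)")
        for _, p, m, M in self.schedule:
            if not (0 < p <= 1 and 0 < m < 1 < M):
                raise ValueError("schedule stages need 0 < p <= 1 and m < 1 < M")


@dataclass
class SearchResult:
    """Outcome of a refinement run."""

    params: np.ndarray
    delta: float
    iterations: int
    accepted: int
    seed: int
    settings: MCSettings
    trace: List[Tuple[int, float]] = field(default_factory=list)

    def converged(self) -> bool:
        return self.delta < self.settings.tol


def screen(
    space: SearchSpace,
    h: float,
    windows: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.5, 1.2), (0.5, 1.3)),
    seed: int = 0,
    max_draws: int = 100_000,
) -> Tuple[np.ndarray, int]:
    """Step 1: random draws until the shape windows are satisfied.

    ``windows = ((gamma_lo, gamma_hi), (rho_lo, rho_hi))``. Returns the
    accepted parameter vector and the number of draws consumed. The
    windows keep the normalized curve near the position/steepness locus of
    the Hill family; candidates outside never refine well.
    """
    (g_lo, g_hi), (r_lo, r_hi) = windows
    rng = np.random.default_rng(seed)
    for draw in range(1, max_draws + 1):
        params = space.sample(rng)
        try:
            g = normalize(binding_polynomial(space, params))
        except ValueError:
            continue
        sh = shape(g)
        if g_lo <= sh.gamma <= g_hi and r_lo <= sh.rho <= r_hi:
            return params, draw
    raise ScreeningError(f"no candidate in {max_draws} draws")


def refine(candidate: np.ndarray, space: SearchSpace, settings: MCSettings) -> SearchResult:
    """Step 2: annealed Monte Carlo descent of the Hill error.

    Improving moves are always kept; worsening moves are kept with
    probability beta. The best-so-far state is tracked separately and is
    what the result reports, so its error is non-increasing by
    construction even with uphill acceptance.
    """
    rng = np.random.default_rng(settings.seed)
    lo, hi = space.log_bounds()
    current = space.clamp(np.asarray(candidate, dtype=float))
    cur_delta = _delta(space, current, settings.h)
    best, best_delta = current.copy(), cur_delta
    trace: List[Tuple[int, float]] = [(0, best_delta)]
    accepted = 0
    iterations = 0
    for it in range(1, settings.max_iter + 1):
        iterations = it
        p, m, M = settings.stage(best_delta)
        mask = rng.random(space.dim) < p
        proposal = current.copy()
        if mask.any():
            idx = np.nonzero(mask)[0]
            factors = np.exp(rng.uniform(math.log(m), math.log(M), size=len(idx)))
            logv = np.clip(np.log(proposal[idx] * factors), lo[idx], hi[idx])
            proposal[idx] = np.exp(logv)
        new_delta = _delta(space, proposal, settings.h)
        if new_delta < cur_delta or rng.random() < settings.beta:
            current, cur_delta = proposal, new_delta
            accepted += 1
            if new_delta < best_delta:
                best, best_delta = proposal.copy(), new_delta
                trace.append((it, best_delta))
        if best_delta < settings.tol:
            break
    return SearchResult(
        params=best,
        delta=best_delta,
        iterations=iterations,
        accepted=accepted,
        seed=settings.seed,
        settings=settings,
        trace=trace,
    )


def evaluate(
    space: SearchSpace, params: np.ndarray, h: float
) -> Tuple[NormalizedCurve, float, EffectiveParams]:
    """Full report for a parameter vector: curve, Hill error, effective table.

    A pure function of its arguments; the effective parameters come from
    the generic conformational-average route, so this also cross-checks the
    fast factorised polynomial used inside the search loop.
    """
    g = normalize(binding_polynomial(space, params))
    delta = hill_error(g, h)
    eff = effective_params(space.to_graph(params))
    return g, delta, eff
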