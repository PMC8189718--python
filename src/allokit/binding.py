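"""Binding functions, normalization, and shape measures.

The partition function of the effective binding hypercube is a polynomial
in ligand concentration, ``Psi(x) = sum_s a_s x**s`` with ``a_0 = 1``, whose
coefficients are sums of ordered products of effective association
constants over binding subsets. Fractional saturation is the logarithmic
derivative ``f(x) = (x / n Psi) dPsi/dx`` — a generalised
Monod-Wyman-Changeux (MWC) formula valid for any conformational ensemble,
which reduces to the classical two-conformation MWC expression.

Shape is quantified on the normalized curve ``g(x) = f(x * u05)`` with
``g(1) = 1/2``: steepness ``rho`` is the maximum of ``dg/dx`` and position
``gamma`` the concentration at which it occurs. Proximity to a Hill
function ``H_h(x) = x**h / (1 + x**h)`` is the mean absolute difference
``delta`` over a fixed 1000-point logarithmic grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp

from .allostery import EMPTY, Subset, mask_subset, subsets
from .effective import EffectiveParams

__all__ = [
    "BindingPolynomial",
    "NormalizedCurve",
    "ShapeMeasures",
    "NormalizationError",
    "partition_polynomial",
    "fractional_saturation",
    "subset_probabilities",
    "site_occupancy",
    "classical_mwc",
    "normalize",
    "shape",
    "hill",
    "hill_error",
    "hill_error_grid",
]

#: the fixed error grid: 1000 logarithmically spaced points between
#: 0.0005 and 5, i.e. 0.0005 * u**j for j = 0..999 with u = 10**(4/999)
HILL_GRID_BASE = 0.0005
HILL_GRID_RATIO = 10 ** (4 / 999)
HILL_GRID_POINTS = 1000


class NormalizationError(ValueError):
    """The binding curve never reaches half-saturation."""


@dataclass
class BindingPolynomial:
    """Partition polynomial ``Psi(x)`` stored as log coefficients.

    ``log_coeffs[s] = log a_s``; ``a_0 = 1`` so ``log_coeffs[0] = 0``.
    """

    log_coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.log_coeffs = np.asarray(self.log_coeffs, dtype=float)
        if self.log_coeffs[0] != 0.0:
            raise ValueError("constant coefficient must be 1")

    @property
    def n(self) -> int:
        return len(self.log_coeffs) - 1

    @property
    def coeffs(self) -> np.ndarray:
        return np.exp(self.log_coeffs)

    def _log_terms(self, x: np.ndarray) -> np.ndarray:
        """log(a_s * x**s) for each s, shape (len(x), n+1)."""
        s = np.arange(self.n + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.log(x)[:, None]
            out = self.log_coeffs[None, :] + s[None, :] * logx
        out[:, 0] = self.log_coeffs[0]  # x**0 term, finite even at x = 0
        return out

    def moments(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """Mean and second moment of the bound count s at concentrations x.

        These are the moments of s under the subset distribution
        ``Pr_S propto a_s x**s`` (collected by size); the mean gives the
        saturation and the variance the slope, via
        ``x f'(x) = (m2 - m1**2) / n``.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        s = np.arange(self.n + 1, dtype=float)
        lt = self._log_terms(x)
        lZ = logsumexp(lt, axis=1)
        w = np.exp(lt - lZ[:, None])
        m1 = w @ s
        m2 = w @ s**2
        return m1, m2


def partition_polynomial(eff: EffectiveParams, n: int | None = None) -> BindingPolynomial:
    """Partition polynomial from effective association constants.

    ``a_s`` sums, over subsets of size s, ordered products of effective
    constants binding the highest site first (each factor's context sits
    above its site, so only independent parameters enter).
    """
    n = eff.n if n is None else n
    log_coeffs = np.empty(n + 1)
    for s in range(n + 1):
        terms = [eff.log_mu_phi(S) for S in subsets(n, size=s)]
        log_coeffs[s] = logsumexp(terms)
    log_coeffs[0] = 0.0
    return BindingPolynomial(log_coeffs=log_coeffs)


def fractional_saturation(poly: BindingPolynomial, x) -> np.ndarray | float:
    """f(x) = (x / n) * Psi'(x) / Psi(x), the average bound fraction."""
    scalar = np.isscalar(x)
    m1, _ = poly.moments(x)
    out = m1 / poly.n
    return float(out[0]) if scalar else out


def subset_probabilities(eff: EffectiveParams, x: float) -> Dict[Subset, float]:
    """Equilibrium probabilities of the binding subsets at concentration x."""
    Ss = subsets(eff.n)
    with np.errstate(divide="ignore"):
        lt = np.array(
            [eff.log_mu_phi(S) + len(S) * np.log(x) for S in Ss]
        )
    lZ = logsumexp(lt)
    return {S: float(p) for S, p in zip(Ss, np.exp(lt - lZ))}


def site_occupancy(eff: EffectiveParams, i: int, x: float) -> float:
    """Average occupancy of site i: total probability of subsets holding i."""
    if not 1 <= i <= eff.n:
        raise ValueError(f"site index {i} out of range")
    probs = subset_probabilities(eff, x)
    return sum(p for S, p in probs.items() if i in S)


def classical_mwc(alpha: float, c: float, L: float, n: int) -> float:
    """The classical two-conformation MWC fractional saturation.

    ``alpha = x * K_R`` and ``c * alpha = x * K_T`` are the scaled
    concentrations for the relaxed and tense conformations and L the
    conformational equilibrium constant of the empty molecule.
    """
    num = alpha * (1 + alpha) ** (n - 1) + c * alpha * L * (1 + c * alpha) ** (n - 1)
    den = (1 + alpha) ** n + L * (1 + c * alpha) ** n
    return num / den


@dataclass
class NormalizedCurve:
    """Binding curve rescaled so that half-saturation sits at x = 1."""

    poly: BindingPolynomial
    u05: float

    def __call__(self, x) -> np.ndarray | float:
        return fractional_saturation(self.poly, np.asarray(x, dtype=float) * self.u05)

    def derivative(self, x) -> np.ndarray | float:
        """dg/dx, from the exact identity x g'(x) = var(s)/n."""
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        m1, m2 = self.poly.moments(x * self.u05)
        out = np.where(x > 0, (m2 - m1**2) / (self.poly.n * np.where(x > 0, x, 1.0)), np.nan)
        # limit x -> 0: slope of m1/n in x; finite only when a_1 > 0
        if np.any(x == 0):
            slope0 = math.exp(self.poly.log_coeffs[1]) * self.u05 / self.poly.n
            out = np.where(x == 0, slope0, out)
        return float(out[0]) if scalar else out


def normalize(poly: BindingPolynomial) -> NormalizedCurve:
    """Solve f(u05) = 1/2 by bracketed bisection on log10 concentration."""
    f = lambda t: fractional_saturation(poly, 10.0**t) - 0.5
    lo, hi = -12.0, 12.0
    if f(lo) > 0 or f(hi) < 0:
        raise NormalizationError("saturation does not cross 1/2 on the search range")
    t = brentq(f, lo, hi, xtol=1e-13)
    return NormalizedCurve(poly=poly, u05=10.0**t)


@dataclass
class ShapeMeasures:
    """Steepness rho (max slope of g) and position gamma (its argmax)."""

    rho: float
    gamma: float
    at_boundary: bool = False


def shape(
    g: NormalizedCurve,
    grid: Tuple[float, float, int] = (1e-3, 1e3, 512),
) -> ShapeMeasures:
    """Maximize the analytic derivative of g over a log grid, then refine.

    A coarse logarithmic scan brackets the maximum and golden-section
    refinement polishes it. If the scan peaks at a grid end the result is
    flagged as a boundary case (e.g. the Hill function with h = 1, whose
    slope is maximal as x -> 0).
    """
    lo, hi, m = grid
    xs = np.geomspace(lo, hi, int(m))
    dg = g.derivative(xs)
    k = int(np.argmax(dg))
    if k == 0 or k == len(xs) - 1:
        return ShapeMeasures(rho=float(dg[k]), gamma=float(xs[k]), at_boundary=True)
    res = minimize_scalar(
        lambda t: -g.derivative(math.exp(t)),
        bounds=(math.log(xs[k - 1]), math.log(xs[k + 1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    gamma = math.exp(res.x)
    return ShapeMeasures(rho=float(-res.fun), gamma=gamma, at_boundary=False)


def hill(h: float, x) -> np.ndarray | float:
    """The Hill function H_h(x) = x**h / (1 + x**h)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = 1.0 / (1.0 + x**-h)
    return float(out) if out.ndim == 0 else out


def hill_error_grid() -> np.ndarray:
    """The fixed evaluation grid: 1000 log-spaced points on [0.0005, 5]."""
    j = np.arange(HILL_GRID_POINTS)
    return HILL_GRID_BASE * HILL_GRID_RATIO**j


def hill_error(g: Callable[[np.ndarray], np.ndarray], h: float) -> float:
    """Mean absolute deviation of g from the Hill function on the fixed grid."""
    xs = hill_error_grid()
    return float(np.mean(np.abs(np.asarray(g(xs)) - hill(h, xs))))
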