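"""Binding polynomials, saturation, normalization, shape, Hill error."""

import math

import numpy as np
import pytest

from allokit.allostery import EMPTY, build, subsets
from allokit.binding import (
    BindingPolynomial,
    NormalizationError,
    NormalizedCurve,
    classical_mwc,
    fractional_saturation,
    hill,
    hill_error,
    hill_error_grid,
    normalize,
    partition_polynomial,
    shape,
    site_occupancy,
    subset_probabilities,
)
from allokit.effective import effective_params
from allokit.graphcore import steady_state
from allokit.interface import FixtureSpec, random_ensemble


def hill_polynomial(h: int) -> NormalizedCurve:
    """Psi = 1 + x^h gives exactly the Hill function as saturation."""
    log_coeffs = np.full(h + 1, -np.inf)
    log_coeffs[0] = 0.0
    log_coeffs[h] = 0.0
    return NormalizedCurve(poly=BindingPolynomial(log_coeffs=log_coeffs), u05=1.0)


class TestPartitionPolynomial:
    def test_single_site(self):
        A = random_ensemble(FixtureSpec(n=1, N=1, seed=1))
        eff = effective_params(A)
        poly = partition_polynomial(eff)
        K = eff.Kphi(1, EMPTY)
        assert poly.coeffs == pytest.approx([1.0, K])

    def test_identical_noncooperative_sites_are_binomial(self):
        K = 2.5
        import allokit.allostery as allo

        table = allo.ConformationTable(
            n=4,
            conformations=["c"],
            log_K_bare={("c", i): math.log(K) for i in range(1, 5)},
        )
        A = allo.AllosteryGraph(
            n=4,
            table=table,
            horiz=allo.HorizontalSpec(conformations=["c"], log_lambda={"c": 0.0}),
        )
        poly = partition_polynomial(effective_params(A))
        expected = [math.comb(4, s) * K**s for s in range(5)]
        assert poly.coeffs == pytest.approx(expected, rel=1e-12)

    def test_two_conformation_partition_function(self, mwc_ensemble):
        """Psi = (1 + x K_R)^n + L (1 + x K_T)^n for the classical ensemble."""
        A, (K_R, K_T, L) = mwc_ensemble
        poly = partition_polynomial(effective_params(A))
        expected = (
            np.polynomial.polynomial.polypow([1, K_R], 4)
            + L * np.polynomial.polynomial.polypow([1, K_T], 4)
        ) / (1 + L)
        assert poly.coeffs == pytest.approx(expected, rel=1e-10)


class TestFractionalSaturation:
    def test_zero_concentration(self, small_ensemble):
        poly = partition_polynomial(effective_params(small_ensemble))
        assert fractional_saturation(poly, 0.0) == 0.0

    def test_single_site_michaelis_form(self):
        poly = BindingPolynomial(log_coeffs=np.array([0.0, math.log(3.0)]))
        for x in (0.01, 0.5, 2.0):
            assert fractional_saturation(poly, x) == pytest.approx(
                3 * x / (1 + 3 * x), rel=1e-12
            )

    def test_three_route_equality(self, small_ensemble):
        """Log-derivative formula, subset-probability sum, and explicit
        graph probabilities all agree."""
        A = small_ensemble
        x = 0.7
        eff = effective_params(A)
        poly = partition_polynomial(eff)
        f1 = fractional_saturation(poly, x)
        probs = subset_probabilities(eff, x)
        f2 = sum(len(Ss) * p for Ss, p in probs.items()) / 2
        ss = steady_state(build(A, x=x))
        f3 = (
            sum(
                bin(m).count("1") * ss.probabilities[(c, m)]
                for c in A.conformations
                for m in range(4)
            )
            / 2
        )
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert f1 == pytest.approx(f3, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_concentration(self, seed):
        A = random_ensemble(FixtureSpec(n=3, N=3, seed=seed, omega_mode="random"))
        poly = partition_polynomial(effective_params(A))
        xs = np.logspace(-6, 6, 200)
        f = fractional_saturation(poly, xs)
        assert np.all(np.diff(f) >= -1e-14)


class TestSiteOccupancy:
    def test_single_site_equals_saturation(self):
        A = random_ensemble(FixtureSpec(n=1, N=2, seed=3))
        eff = effective_params(A)
        poly = partition_polynomial(eff)
        for x in (0.1, 1.0, 7.0):
            assert site_occupancy(eff, 1, x) == pytest.approx(
                fractional_saturation(poly, x), rel=1e-12
            )

    def test_symmetric_sites_have_identical_curves(self, mwc_ensemble):
        A, _ = mwc_ensemble
        eff = effective_params(A)
        for x in (0.05, 0.8, 4.0):
            occs = [site_occupancy(eff, i, x) for i in range(1, 5)]
            assert occs == pytest.approx([occs[0]] * 4, rel=1e-12)

    def test_occupancies_sum_to_n_times_saturation(self):
        A = random_ensemble(FixtureSpec(n=4, N=2, seed=6, omega_mode="random"))
        eff = effective_params(A)
        poly = partition_polynomial(eff)
        x = 0.37
        total = sum(site_occupancy(eff, i, x) for i in range(1, 5))
        assert total / 4 == pytest.approx(fractional_saturation(poly, x), abs=1e-12)


class TestClassicalMwc:
    def test_symmetric_point(self):
        for L in (0.0, 1.0, 100.0):
            assert classical_mwc(1.0, 1.0, L, 4) == pytest.approx(0.5)

    def test_single_conformation_limit(self):
        for a in (0.2, 1.0, 5.0):
            assert classical_mwc(a, 0.3, 0.0, 4) == pytest.approx(a / (1 + a))

    @pytest.mark.parametrize("seed", range(5))
    def test_recovered_by_generalised_route(self, seed):
        import allokit.allostery as allo

        rng = np.random.default_rng(seed)
        K_R, K_T = rng.uniform(0.1, 10.0, 2)
        L = float(rng.uniform(0.01, 100.0))
        n = int(rng.integers(2, 6))
        confs = ["R", "T"]
        table = allo.ConformationTable(
            n=n,
            conformations=confs,
            log_K_bare={
                (c, i): math.log(K)
                for c, K in zip(confs, (K_R, K_T))
                for i in range(1, n + 1)
            },
        )
        A = allo.AllosteryGraph(
            n=n,
            table=table,
            horiz=allo.HorizontalSpec(
                conformations=confs, log_lambda={"R": 0.0, "T": math.log(L)}
            ),
        )
        poly = partition_polynomial(effective_params(A))
        for x in rng.uniform(0.01, 5.0, 4):
            alpha = x * K_R
            c = K_T / K_R
            assert fractional_saturation(poly, float(x)) == pytest.approx(
                classical_mwc(alpha, c, L, n), rel=1e-10
            )


class TestNormalize:
    def test_hill_curve_already_normalized(self):
        g = hill_polynomial(4)
        renorm = normalize(g.poly)
        assert renorm.u05 == pytest.approx(1.0, abs=1e-10)
        assert g(1.0) == pytest.approx(0.5)

    def test_michaelis_half_point(self):
        K = 7.3
        poly = BindingPolynomial(log_coeffs=np.array([0.0, math.log(K)]))
        assert normalize(poly).u05 == pytest.approx(1 / K, rel=1e-9)

    def test_random_ensemble_normalizes_to_half(self):
        A = random_ensemble(FixtureSpec(n=4, N=3, seed=12, omega_mode="random"))
        g = normalize(partition_polynomial(effective_params(A)))
        assert g(1.0) == pytest.approx(0.5, abs=1e-10)

    def test_out_of_range_half_point_raises(self):
        poly = BindingPolynomial(log_coeffs=np.array([0.0, math.log(1e-15)]))
        with pytest.raises(NormalizationError):
            normalize(poly)


class TestShape:
    def test_hyperbolic_curve_peaks_at_origin(self):
        sm = shape(hill_polynomial(1))
        assert sm.at_boundary
        assert sm.rho == pytest.approx(1.0, abs=5e-3)

    @pytest.mark.parametrize("h", [2, 4, 6])
    def test_hill_shape_closed_form(self, h):
        # dH_h/dx = h x^(h-1) / (1+x^h)^2 is maximal at x* = ((h-1)/(h+1))^(1/h)
        sm = shape(hill_polynomial(h))
        x_star = ((h - 1) / (h + 1)) ** (1 / h)
        rho_star = h * x_star ** (h - 1) / (1 + x_star**h) ** 2
        assert not sm.at_boundary
        assert sm.gamma == pytest.approx(x_star, rel=1e-6)
        assert sm.rho == pytest.approx(rho_star, rel=1e-9)

    def test_idempotent_under_renormalization(self):
        A = random_ensemble(FixtureSpec(n=4, N=3, seed=12, omega_mode="random"))
        g = normalize(partition_polynomial(effective_params(A)))
        s1, s2 = shape(g), shape(normalize(g.poly))
        assert s1.rho == pytest.approx(s2.rho, rel=1e-9)
        assert s1.gamma == pytest.approx(s2.gamma, rel=1e-6)


class TestHillError:
    def test_grid_spans_stated_range(self):
        xs = hill_error_grid()
        assert len(xs) == 1000
        assert xs[0] == pytest.approx(0.0005)
        assert xs[-1] == pytest.approx(5.0)

    def test_identity_is_zero(self):
        g = hill_polynomial(4)
        assert hill_error(g, 4) == pytest.approx(0.0, abs=1e-15)

    def test_distinct_hill_functions_differ(self):
        g = hill_polynomial(4)
        assert hill_error(g, 6) > 0.01

    def test_refined_grid_agrees_to_discretization_error(self):
        g = hill_polynomial(4)
        coarse = hill_error(g, 6)
        xs = np.geomspace(0.0005, 5.0, 100_000)
        fine = float(np.mean(np.abs(g(xs) - hill(6, xs))))
        assert coarse == pytest.approx(fine, abs=5e-4)
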