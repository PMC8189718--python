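"""Higher-order measures: HOCs, residual free energies, couplings."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokit.homeasures import (
    CouplingSpec,
    FreeEnergyLandscape,
    coupling,
    coupling_from_hoc,
    hoc_from_landscape,
    hoc_table,
    residual_energies,
    residual_from_hoc,
)

from conftest import random_landscape

TOY = FreeEnergyLandscape(
    n=2,
    DeltaPhi={
        frozenset(): 0.0,
        frozenset({1}): 1.0,
        frozenset({2}): 2.0,
        frozenset({1, 2}): 4.0,
    },
)


def additive_landscape(n, energies, offset=0.0):
    from allokit.allostery import subsets

    return FreeEnergyLandscape(
        n=n,
        DeltaPhi={S: offset + sum(energies[i - 1] for i in S) for S in subsets(n)},
    )


class TestHocFromLandscape:
    def test_additive_landscape_has_no_cooperativity(self):
        L = additive_landscape(3, [0.5, -1.0, 2.0], offset=0.7)
        for (i, S), w in hoc_table(L).items():
            assert w == pytest.approx(1.0, rel=1e-12)

    def test_toy_value(self):
        # omega[1,{2}] = exp(-[(4-2) - (1-0)]) = e^-1
        assert hoc_from_landscape(TOY, 1, frozenset({2})) == pytest.approx(
            math.exp(-1)
        )

    def test_round_trip_landscape_recovery(self):
        """Bare constants and HOCs recover the landscape up to the zero point."""
        L = random_landscape(4, seed=2)
        omega = hoc_table(L)
        P = L.DeltaPhi
        E = frozenset()
        for S in P:
            # Phi_S - Phi_empty rebuilt by binding highest site first
            sites = sorted(S)
            total = 0.0
            for k, i in enumerate(sites):
                ctx = frozenset(sites[k + 1:])
                logK_bare = -(P[frozenset({i})] - P[E])
                total += logK_bare + math.log(omega[(i, ctx)])
            assert -total == pytest.approx(P[S] - P[E], abs=1e-9)

    def test_occupied_site_rejected(self):
        with pytest.raises(ValueError):
            hoc_from_landscape(TOY, 1, frozenset({1, 2}))


class TestResidualEnergies:
    def test_singleton_residual_is_energy_difference(self):
        res = residual_energies(TOY).DeltaPhiRes
        assert res[frozenset({1})] == pytest.approx(1.0)
        assert res[frozenset({2})] == pytest.approx(2.0)

    def test_toy_pair_by_inclusion_exclusion(self):
        res = residual_energies(TOY, route="inclusion-exclusion").DeltaPhiRes
        assert res[frozenset({1, 2})] == pytest.approx(4 - 1 - 2 + 0)

    def test_additive_landscape_has_no_synergy(self):
        L = additive_landscape(4, [1.0, 0.2, -0.7, 3.0], offset=-1.0)
        res = residual_energies(L).DeltaPhiRes
        for S, v in res.items():
            if len(S) >= 2:
                assert v == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_both_routes_agree(self, n):
        L = random_landscape(n, seed=n)
        r1 = residual_energies(L, route="recursion").DeltaPhiRes
        r2 = residual_energies(L, route="inclusion-exclusion").DeltaPhiRes
        for S in r1:
            assert r1[S] == pytest.approx(r2[S], abs=1e-9)

    def test_reconstruction_is_exact(self):
        L = random_landscape(4, seed=9)
        rebuilt = residual_energies(L).reconstruct()
        for S, v in L.DeltaPhi.items():
            assert rebuilt[S] == pytest.approx(v, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        min_size=8,
        max_size=8,
    )
)
def test_measure_triangle_on_arbitrary_landscapes(energies):
    """landscape -> HOCs -> residuals equals landscape -> residuals, and
    residuals reconstruct the landscape, for any finite 3-site energies."""
    from allokit.allostery import subsets

    L = FreeEnergyLandscape(
        n=3, DeltaPhi=dict(zip(subsets(3), energies))
    )
    res = residual_energies(L).DeltaPhiRes
    omega = hoc_table(L)
    for S in subsets(3):
        if len(S) >= 2:
            assert residual_from_hoc(omega, S) == pytest.approx(
                math.exp(-res[S]), rel=1e-8, abs=1e-10
            )
    rebuilt = residual_energies(L).reconstruct()
    for S, v in L.DeltaPhi.items():
        assert rebuilt[S] == pytest.approx(v, abs=1e-9)


class TestResidualFromHoc:
    def test_pair_is_single_hoc(self):
        L = random_landscape(3, seed=1)
        omega = hoc_table(L)
        for i, j in itertools.combinations(range(1, 4), 2):
            assert residual_from_hoc(omega, frozenset({i, j})) == pytest.approx(
                omega[(i, frozenset({j}))], rel=1e-12
            )

    def test_triple_formula(self):
        L = random_landscape(3, seed=4)
        omega = hoc_table(L)
        S = frozenset({1, 2, 3})
        expected = omega[(1, frozenset({2, 3}))] / (
            omega[(1, frozenset({2}))] * omega[(1, frozenset({3}))]
        )
        assert residual_from_hoc(omega, S, i=1) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_cross_route_and_anchor_invariance(self, n):
        L = random_landscape(n, seed=10 + n)
        omega = hoc_table(L)
        res = residual_energies(L).DeltaPhiRes
        from allokit.allostery import subsets

        for S in subsets(n):
            if len(S) < 2:
                continue
            values = [residual_from_hoc(omega, S, i=i) for i in sorted(S)]
            for v in values:
                assert v == pytest.approx(values[0], rel=1e-10)
                assert v == pytest.approx(math.exp(-res[S]), rel=1e-9)

    def test_small_subsets_rejected(self):
        with pytest.raises(ValueError):
            residual_from_hoc({}, frozenset({1}))


class TestCoupling:
    def test_double_mutant_cycle_value(self):
        spec = CouplingSpec(offset=frozenset(), sequence=(1, 2))
        assert coupling(TOY, spec) == pytest.approx(4 - 2 - (1 - 0))

    def test_pairwise_permutation_symmetry(self):
        assert coupling(TOY, CouplingSpec(frozenset(), (1, 2))) == pytest.approx(
            coupling(TOY, CouplingSpec(frozenset(), (2, 1)))
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_full_permutation_symmetry(self, k):
        L = random_landscape(5, seed=20 + k)
        base = tuple(range(1, k + 1))
        Z = frozenset({5}) if k < 5 else frozenset()
        ref = coupling(L, CouplingSpec(Z, base))
        for perm in itertools.permutations(base):
            assert coupling(L, CouplingSpec(Z, perm)) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_couplings_at_empty_offset_are_residuals(self, k):
        L = random_landscape(4, seed=30 + k)
        res = residual_energies(L).DeltaPhiRes
        seq = tuple(range(1, k + 1))
        assert coupling(L, CouplingSpec(frozenset(), seq)) == pytest.approx(
            res[frozenset(seq)], abs=1e-10
        )

    def test_overlapping_offset_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(offset=frozenset({1}), sequence=(1, 2))


class TestCouplingFromHoc:
    def test_second_order_is_hoc_ratio(self):
        L = random_landscape(4, seed=40)
        omega = hoc_table(L)
        Z = frozenset({3})
        val = coupling_from_hoc(omega, CouplingSpec(Z, (1, 2)))
        assert val == pytest.approx(
            omega[(1, Z | {2})] / omega[(1, Z)], rel=1e-12
        )

    def test_third_order_formula(self):
        L = random_landscape(4, seed=41)
        omega = hoc_table(L)
        Z = frozenset({4})
        expected = (
            omega[(1, Z | {2, 3})]
            * omega[(1, Z)]
            / (omega[(1, Z | {2})] * omega[(1, Z | {3})])
        )
        assert coupling_from_hoc(omega, CouplingSpec(Z, (1, 2, 3))) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_cross_route_against_landscape(self, k):
        L = random_landscape(5, seed=50 + k)
        omega = hoc_table(L)
        spec = CouplingSpec(frozenset({5}), tuple(range(1, k + 1)))
        via_hoc = coupling_from_hoc(omega, spec)
        via_landscape = math.exp(-coupling(L, spec))
        assert via_hoc == pytest.approx(via_landscape, rel=1e-9)

    def test_first_order_rejected(self):
        with pytest.raises(ValueError):
            coupling_from_hoc({}, CouplingSpec(frozenset(), (1,)))
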