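"""n-pearl energy landscape: energies, extrema, stability, simplex geometry."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pearlnecklace import (
    AsymmetryState,
    SimplexPoint,
    chi_critical,
    energy,
    equilibrated_energy,
    find_extremum,
    in_simplex,
    stability_transition,
    symmetric_energy,
    vertex,
)


class TestEnergy:
    def test_reference_state_is_zero(self):
        st = AsymmetryState(n=1, chi=5.0, x=(0.0,), y=(0.0,))
        assert energy(st) == 0.0

    @pytest.mark.parametrize("chi,expected", [
        (0.0, 2 ** (1 / 3) - 1),            # pure surface cost of splitting
        (2.0, 2 * 2 ** (1 / 3) - 3),        # electrostatics now favors splitting
    ])
    def test_symmetric_two_pearl_values(self, chi, expected):
        st = AsymmetryState(n=2, chi=chi, x=(0.0, 0.0), y=(0.0, 0.0))
        assert energy(st) == pytest.approx(expected, abs=1e-12)
        assert symmetric_energy(2, chi) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_three_pearls(self):
        assert symmetric_energy(3, 3.0) == pytest.approx(2 * 3 ** (1 / 3) - 4, abs=1e-12)

    def test_energy_matches_symmetric_form(self):
        for n in range(1, 6):
            st = AsymmetryState(n=n, chi=1.3, x=(0.0,) * n, y=(0.0,) * n)
            assert energy(st) == pytest.approx(symmetric_energy(n, 1.3), abs=1e-12)

    def test_vertex_state_reduces_to_reference(self):
        # one pearl holding all mass and charge, one empty pearl
        st = AsymmetryState(n=2, chi=1.7, x=(0.5, -0.5), y=(0.5, -0.5))
        assert energy(st) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mass_with_charge_rejected(self):
        st = AsymmetryState(n=2, chi=1.0, x=(0.5, -0.5), y=(0.0, 0.0))
        with pytest.raises(ValueError, match="zero-mass"):
            energy(st)

    def test_negative_mass_rejected(self):
        st = AsymmetryState(n=2, chi=1.0, x=(0.6, -0.6), y=(0.5, -0.5))
        with pytest.raises(ValueError, match="negative"):
            energy(st)

    def test_constraint_violation_rejected(self):
        with pytest.raises(ValueError):
            AsymmetryState(n=2, chi=1.0, x=(0.1, 0.1), y=(0.0, 0.0))


class TestEquilibratedEnergy:
    def test_equal_masses_give_symmetric_energy(self):
        for n in (2, 3, 4):
            e, y = equilibrated_energy(np.full(n, 1 / n), 1.2)
            assert e == pytest.approx(symmetric_energy(n, 1.2), abs=1e-12)
            assert np.allclose(y, 0.0, atol=1e-12)

    def test_single_massive_pearl_is_reference(self):
        e, y = equilibrated_energy([1.0, 0.0], 2.4)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert y[0] == pytest.approx(0.5)   # all charge on the massive pearl

    def test_agrees_with_numerical_minimizer(self):
        # closed-form charge equilibration vs generic constrained minimization
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            chi = float(rng.uniform(0.1, 4.0))
            m = rng.dirichlet(np.ones(n))
            e_closed, y_star = equilibrated_energy(m, chi)

            def obj(qfree):
                q = np.concatenate([qfree, [1.0 - qfree.sum()]])
                return float(np.sum(m ** (2 / 3)) + chi * np.sum(q ** 2 / m ** (1 / 3))
                             - 1 - chi)

            res = minimize(obj, np.full(n - 1, 1 / n), method="BFGS", tol=1e-12)
            assert e_closed == pytest.approx(res.fun, abs=1e-8)
            assert np.allclose(1 / n + y_star,
                               m ** (1 / 3) / np.sum(m ** (1 / 3)), atol=1e-12)

    def test_consistency_with_full_energy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 5))
            m = rng.dirichlet(np.ones(n))
            chi = float(rng.uniform(0, 3))
            e_eq, y_star = equilibrated_energy(m, chi)
            st = AsymmetryState(n=n, chi=chi, x=tuple(m - 1 / n), y=tuple(y_star))
            assert energy(st) == pytest.approx(e_eq, abs=1e-10)

    def test_mass_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            equilibrated_energy([0.6, 0.6], 1.0)


class TestExtrema:
    def test_zero_chi_extremum_is_vertex_minimum(self):
        rec = find_extremum(2, 1, 0.0)
        assert rec.mass_large == pytest.approx(1.0)
        assert rec.mass_small == pytest.approx(0.0)
        assert rec.energy == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_state_is_saddle_below_transition(self):
        rec = find_extremum(2, 2, 1.0)
        assert rec.stability == "saddle"
        assert rec.n_negative == 1

    def test_symmetric_state_is_minimum_above_transition(self):
        rec = find_extremum(3, 3, 4.0)
        assert rec.stability == "minimum"

    def test_one_large_pearl_is_global_among_extrema(self):
        # absolute minimum: one large pearl with n-1 equal small pearls
        recs = {nl: find_extremum(3, nl, 1.0) for nl in (1, 2, 3)}
        assert recs[1].energy < recs[2].energy < recs[3].energy
        assert recs[1].stability == "minimum"

    @pytest.mark.parametrize("n", [3, 4])
    def test_saddle_energy_ordering(self, n):
        # E(n,0) >= E(n-1,1) >= ... >= E(1,n-1) below the transition
        for chi in (0.5, 1.0):
            energies = [find_extremum(n, nl, chi).energy for nl in range(n, 0, -1)]
            assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_saddle_index_increases_with_nl(self):
        # each extra large pearl adds one downhill direction
        assert find_extremum(3, 1, 1.0).n_negative == 0
        assert find_extremum(3, 2, 1.0).n_negative == 1
        assert find_extremum(3, 3, 1.0).n_negative == 2

    def test_absent_beyond_fold(self):
        assert find_extremum(2, 1, 2.5) is None
        assert find_extremum(3, 1, 3.5) is None

    def test_bracketing_around_fold(self):
        chic = chi_critical(3, 1)
        assert find_extremum(3, 1, chic - 1e-4) is not None
        assert find_extremum(3, 1, chic + 1e-4) is None

    def test_upper_branch_exists_between_n_and_fold(self):
        chic = chi_critical(3, 1)
        mid = 0.5 * (3.0 + chic)
        lower = find_extremum(3, 1, mid, branch="primary")
        upper = find_extremum(3, 1, mid, branch="upper")
        assert lower is not None and upper is not None
        assert upper.mass_small > lower.mass_small

    @pytest.mark.parametrize("n,nl", [(2, 1), (3, 1), (3, 2), (4, 1), (4, 2), (4, 3)])
    def test_zero_charge_limit_reaches_vertex(self, n, nl):
        rec = find_extremum(n, nl, 1e-8)
        v = vertex(n, nl)
        assert np.linalg.norm(rec.simplex_point.x_full - v.x_full) < 1e-6

    def test_brute_force_grid_locates_same_minimum(self):
        # independent oracle: dense scan of the two-pearl landscape
        chi = 1.0
        a = np.arange(0.5, 1.0, 1e-3)
        b = 1.0 - a
        e = a ** (2 / 3) + b ** (2 / 3) + chi / (a ** (1 / 3) + b ** (1 / 3)) - 1 - chi
        rec = find_extremum(2, 1, chi)
        assert abs(a[np.argmin(e)] - rec.mass_large) <= 2e-3
        assert e.min() == pytest.approx(rec.energy, abs=1e-5)


class TestChiCritical:
    def test_fold_exceeds_n_for_one_large_pearl_branches(self):
        assert chi_critical(3, 1) > 3.0
        assert chi_critical(4, 1) > 4.0

    def test_two_pearl_branch_merges_at_transition(self):
        # for n = 2 the asymmetric branch terminates exactly at chi = n:
        # chi(u) = 2 - (16/9) u^2 + O(u^4) near the symmetric point
        assert chi_critical(2, 1) == pytest.approx(2.0, abs=1e-9)

    def test_invalid_nl_rejected(self):
        with pytest.raises(ValueError):
            chi_critical(3, 3)


class TestStabilityTransition:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_transition_at_chi_equal_n(self, n):
        assert stability_transition(n) == pytest.approx(n, abs=1e-3)

    def test_n_one_rejected(self):
        with pytest.raises(ValueError):
            stability_transition(1)


class TestSimplexGeometry:
    def test_vertex_examples(self):
        assert np.allclose(vertex(3, 1).x_full, [2 / 3, -1 / 3, -1 / 3])
        assert np.allclose(vertex(2, 1).x_full, [0.5, -0.5])
        assert np.allclose(vertex(4, 4).x_full, np.zeros(4))

    def test_vertex_range_check(self):
        with pytest.raises(ValueError):
            vertex(3, 0)
        with pytest.raises(ValueError):
            vertex(3, 4)

    def test_in_simplex_interior_and_violations(self):
        ok, _ = in_simplex(SimplexPoint(n=3, coords=(0.1, 0.05)))
        assert ok
        bad, violations = in_simplex(SimplexPoint(n=3, coords=(0.05, 0.1)))
        assert not bad and any("ranking" in v for v in violations)

    def test_vertices_lie_in_closed_simplex(self):
        for n in (2, 3, 4, 5):
            for nl in range(1, n + 1):
                ok, violations = in_simplex(vertex(n, nl))
                assert ok, violations

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            SimplexPoint(n=3, coords=(0.1,))

    def test_from_masses_sorts_descending(self):
        p = SimplexPoint.from_masses([0.2, 0.5, 0.3])
        assert np.allclose(p.x_full, [0.5 - 1 / 3, 0.3 - 1 / 3, 0.2 - 1 / 3])
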