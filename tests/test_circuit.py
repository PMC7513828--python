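"""Unit and property tests for the fate-choice circuit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from icmfate.circuit import (CircuitParams, StepSizeError, diagonal_fixed_point,
                             find_equilibria, integrate_population, mean_field,
                             nanog_rhs, nullclines, production, two_cluster_rhs)


def formula_production(x, field, p):
    # independent literal transcription of the production term
    act = (1.0 + x ** p.n) ** p.m
    return p.alpha * act / (act + (field / p.K) ** (2 * p.m))


class TestProduction:
    def test_no_repression_gives_alpha(self, params):
        assert production(0.0, 0.0, params) == pytest.approx(params.alpha)

    def test_field_at_K_halves_basal_rate(self, params):
        assert production(0.0, params.K, params) == pytest.approx(params.alpha / 2)

    def test_strong_field_suppresses(self, params):
        assert production(1.0, 1e6, params) < 1e-6

    def test_matches_direct_formula(self, params):
        # frozen from an independent evaluation: alpha*(1+1)^2/((1+1)^2+1) = 4.0
        assert production(1.0, 1.0, params) == pytest.approx(4.0)
        for x in (0.3, 1.7, 4.2):
            for f in (0.1, 1.0, 3.3):
                assert production(x, f, params) == pytest.approx(
                    formula_production(x, f, params))

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            production(-0.1, 1.0, params)
        with pytest.raises(ValueError):
            production(1.0, -0.1, params)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 5), f=st.floats(0, 50))
    def test_bounded_in_zero_alpha(self, x, f):
        p = CircuitParams()
        v = production(x, f, p)
        assert 0.0 < v <= p.alpha


class TestRhs:
    def test_origin_rate_is_alpha(self, params):
        assert nanog_rhs(0.0, 0.0, params) == pytest.approx(params.alpha)

    def test_decay_dominates_under_saturation(self, params):
        assert nanog_rhs(params.alpha, 1e9, params) == pytest.approx(-params.alpha)

    def test_bisection_root_equals_symmetric_fixed_point(self, params):
        root = bisect(lambda x: nanog_rhs(x, x, params), 1e-6, params.alpha,
                      xtol=1e-10)
        assert root == pytest.approx(diagonal_fixed_point(params), abs=1e-8)


class TestTwoCluster:
    def test_diagonal_symmetry(self, params):
        for c in (0.2, 1.0, 3.0):
            fa, fb = two_cluster_rhs(c, c, params)
            assert fa == pytest.approx(fb)

    def test_origin(self, params):
        fa, fb = two_cluster_rhs(0.0, 0.0, params)
        assert (fa, fb) == pytest.approx((params.alpha, params.alpha))

    def test_swap_equivariance_and_formula_grid(self, params):
        grid = np.linspace(0.1, params.alpha, 5)
        for xa in grid:
            for xb in grid:
                fa, fb = two_cluster_rhs(xa, xb, params)
                fb2, fa2 = two_cluster_rhs(xb, xa, params)
                assert (fa, fb) == pytest.approx((fa2, fb2))
                shared = (xa + xb) / 2
                assert fa == pytest.approx(
                    formula_production(xa, shared, params) - xa)
                assert fb == pytest.approx(
                    formula_production(xb, shared, params) - xb)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            two_cluster_rhs(-1.0, 1.0, params)


class TestNullclines:
    def test_points_are_roots(self, params):
        na, nb = nullclines(params, grid=100)
        for xa, xb in na[::10]:
            assert abs(two_cluster_rhs(xa, xb, params)[0]) < 1e-8
        for xa, xb in nb[::10]:
            assert abs(two_cluster_rhs(xa, xb, params)[1]) < 1e-8

    def test_mirror_symmetry(self, params):
        na, nb = nullclines(params, grid=100)
        np.testing.assert_allclose(na[:, ::-1], nb, atol=1e-12)

    def test_intersections_are_equilibria(self, params):
        na, _ = nullclines(params, grid=400)
        eqs = find_equilibria(params)
        # every equilibrium lies on nullcline A within grid resolution
        for eq in eqs:
            d = np.min(np.linalg.norm(na - np.array(eq.point), axis=1))
            assert d < params.alpha / 100

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            nullclines(params, grid=[])


class TestEquilibria:
    def test_bistable_portrait(self, params):
        eqs = find_equilibria(params)
        assert len(eqs) == 3
        assert sum(e.is_stable for e in eqs) == 2
        unstable = [e for e in eqs if not e.is_stable]
        assert len(unstable) == 1 and unstable[0].on_diagonal

    def test_diagonal_fixed_point_always_present(self, params):
        eqs = find_equilibria(params)
        diag = [e for e in eqs if e.on_diagonal]
        assert len(diag) == 1
        assert diag[0].point[0] == pytest.approx(diagonal_fixed_point(params),
                                                 abs=1e-6)

    def test_mirror_pair(self, params):
        stable = sorted(e.point for e in find_equilibria(params) if e.is_stable)
        assert stable[0] == pytest.approx(stable[1][::-1])

    def test_stability_labels_match_simulation(self, params):
        # perturbations of a stable point decay; of the saddle, grow off-diagonal
        eqs = find_equilibria(params)
        stable = next(e for e in eqs if e.is_stable)
        saddle = next(e for e in eqs if not e.is_stable)
        A = np.ones((2, 2), dtype=bool)
        x0 = np.array(stable.point) + [0.01, -0.01]
        _, traj = integrate_population(x0, A, params, dt=0.01, t_end=20.0)
        assert np.linalg.norm(traj[-1] - stable.point) < 1e-3
        x0 = np.array(saddle.point) + [0.01, -0.01]
        _, traj = integrate_population(x0, A, params, dt=0.01, t_end=20.0)
        assert np.linalg.norm(traj[-1] - saddle.point) > 1.0


class TestIntegratePopulation:
    def test_single_cell_converges_to_diagonal_root(self, params):
        A = np.ones((1, 1), dtype=bool)
        _, traj = integrate_population([0.5], A, params, dt=0.01, t_end=40.0)
        assert traj[-1][0] == pytest.approx(diagonal_fixed_point(params), abs=1e-4)

    def test_two_block_state_is_invariant(self, params):
        stable = next(e for e in find_equilibria(params) if e.is_stable)
        xa, xb = stable.point
        x0 = [xa] * 3 + [xb] * 3
        A = np.ones((6, 6), dtype=bool)
        _, traj = integrate_population(x0, A, params, dt=0.01, t_end=10.0)
        np.testing.assert_allclose(traj[-1], x0, atol=1e-6)

    def test_two_block_matches_two_cluster_reduction(self, params):
        # equal blocks on the complete graph reduce exactly to the planar system
        x0 = [3.1] * 3 + [2.2] * 3
        A = np.ones((6, 6), dtype=bool)
        _, traj = integrate_population(x0, A, params, dt=0.005, t_end=2.0)

        def planar(t, v):
            return two_cluster_rhs(v[0], v[1], params)

        sol = solve_ivp(planar, (0, 2.0), [3.1, 2.2], rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj[-1][:3], sol.y[0, -1], rtol=1e-2)
        np.testing.assert_allclose(traj[-1][3:], sol.y[1, -1], rtol=1e-2)

    def test_permutation_equivariance(self, params):
        rng = np.random.default_rng(0)
        n = 5
        x0 = rng.uniform(0, params.alpha, n)
        A = rng.random((n, n)) < 0.5
        A |= A.T
        np.fill_diagonal(A, True)
        perm = rng.permutation(n)
        _, t1 = integrate_population(x0, A, params, dt=0.01, t_end=1.0)
        _, t2 = integrate_population(x0[perm], A[np.ix_(perm, perm)], params,
                                     dt=0.01, t_end=1.0)
        np.testing.assert_allclose(t1[-1][perm], t2[-1], atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_boundedness(self, seed):
        p = CircuitParams()
        rng = np.random.default_rng(seed)
        n = 4
        x0 = rng.uniform(0, p.alpha, n)
        A = np.eye(n, dtype=bool) | (rng.random((n, n)) < 0.6)
        A |= A.T
        _, traj = integrate_population(x0, A, p, dt=0.01, t_end=5.0)
        assert traj.min() >= 0.0 and traj.max() <= p.alpha * (1 + 1e-9)

    def test_large_step_raises(self, params):
        A = np.ones((1, 1), dtype=bool)
        with pytest.raises(StepSizeError):
            integrate_population([0.0], A, params, dt=5.0, t_end=50.0)

    def test_missing_self_loop_rejected(self, params):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = A[1, 0] = True
        with pytest.raises(ValueError):
            integrate_population([1.0, 1.0], A, params)


def test_mean_field_between_neighborhood_extremes():
    x = np.array([0.0, 2.0, 5.0])
    A = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool)
    mf = mean_field(x, A)
    for i in range(3):
        nb = x[A[i]]
        assert nb.min() <= mf[i] <= nb.max()


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CircuitParams(alpha=-1)
    with pytest.raises(ValueError):
        CircuitParams(K=0)
    with pytest.raises(ValueError):
        CircuitParams(n=0)
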