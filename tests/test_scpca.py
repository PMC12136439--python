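import numpy as np
import pytest

from oracles import brute_force_max_projection

from cyclorder.preprocessing import from_array, standardize
from cyclorder.scpca import (
    approximation_error,
    fit_multistart,
    fit_once,
    objective_value,
    project_v,
    soft_threshold,
    update_d,
    update_u,
)


class TestUpdateU:
    def test_three_four_five(self):
        X = np.array([[3.0, 4.0], [3.0, 4.0], [3.0, 4.0]])
        u1, u2 = update_u(X, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(u1, 0.6)
        np.testing.assert_allclose(u2, 0.8)

    def test_idempotent_on_unit_circle(self, rng):
        theta = rng.uniform(0, 2 * np.pi, size=7)
        X = np.column_stack([np.cos(theta), np.sin(theta)])
        u1, u2 = update_u(X, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(u1, np.cos(theta), atol=1e-12)
        np.testing.assert_allclose(u2, np.sin(theta), atol=1e-12)

    def test_rows_on_unit_circle(self, rng):
        X = rng.normal(size=(30, 12))
        v1 = rng.normal(size=12)
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=12)
        v2 /= np.linalg.norm(v2)
        u1, u2 = update_u(X, v1, v2)
        np.testing.assert_allclose(u1**2 + u2**2, 1.0, atol=1e-12)

    def test_zero_radius_fallback_warns(self):
        X = np.zeros((3, 2))
        X[1:] = [[1.0, 0.0], [0.0, 1.0]]
        with pytest.warns(RuntimeWarning, match="origin"):
            u1, u2 = update_u(X, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert u1[0] == 1.0 and u2[0] == 0.0


class TestProjectV:
    def test_s1_selects_largest_coordinate(self):
        v = project_v(np.array([3.0, 1.0, 0.0]), 1.0)
        np.testing.assert_allclose(v, [1.0, 0.0, 0.0])

    def test_no_thresholding_when_budget_slack(self):
        w = np.array([1.0, 1.0]) / np.sqrt(2)
        v = project_v(w, np.sqrt(2))
        np.testing.assert_allclose(v, w)

    def test_sign_pattern_and_constraints(self, rng):
        for _ in range(50):
            p = int(rng.integers(3, 40))
            w = rng.normal(size=p)
            s = float(rng.uniform(1.0, np.sqrt(p)))
            v = project_v(w, s)
            assert abs(np.linalg.norm(v) - 1.0) < 1e-10
            assert np.abs(v).sum() <= s + 1e-8
            nz = v != 0
            assert np.all(np.sign(v[nz]) == np.sign(w[nz]))

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for i in range(100):
            p = int(rng.integers(3, 13))
            w = rng.normal(size=p)
            s = float(rng.uniform(1.0, np.sqrt(p)))
            v = project_v(w, s)
            oracle = brute_force_max_projection(w, s, seed=i)
            worst = max(worst, oracle - w @ v)
        assert worst < 1e-4

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError, match="zero vector"):
            project_v(np.zeros(4), 1.5)

    def test_s_below_one_is_error(self):
        with pytest.raises(ValueError, match=">= 1"):
            project_v(np.ones(4), 0.5)


class TestUpdateD:
    def _factors(self, n=12, p=8):
        t = np.arange(n) / n
        u1, u2 = np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)
        v1 = np.zeros(p)
        v1[0] = 1.0
        v2 = np.zeros(p)
        v2[1] = 1.0
        return u1, u2, v1, v2

    def test_recovers_scale_from_constructed_matrix(self):
        u1, u2, v1, v2 = self._factors()
        d0 = 2.75
        X = d0 * (np.outer(u1, v1) + np.outer(u2, v2))
        assert abs(update_d(X, u1, u2, v1, v2) - d0) < 1e-10

    def test_zero_matrix(self):
        u1, u2, v1, v2 = self._factors()
        assert update_d(np.zeros((12, 8)), u1, u2, v1, v2) == 0.0

    def test_linear_in_X(self, rng):
        u1, u2, v1, v2 = self._factors()
        X = np.outer(u1, v1) + 0.3 * rng.normal(size=(12, 8))
        d1 = update_d(X, u1, u2, v1, v2)
        d2 = update_d(2 * X, u1, u2, v1, v2)
        assert d1 > 0
        assert abs(d2 - 2 * d1) < 1e-12


class TestFitOnce:
    def test_noiseless_structure_recovered(self, noiseless_cycle):
        # raw matrix: equally spaced sinusoids are already column-centered,
        # and the flat features are exactly zero (z-scoring is undefined)
        X, t, phases = noiseless_cycle
        fit = fit_once(X, s=np.sqrt(10), seed=3)
        assert fit.approx_error / np.sum(X**2) < 0.01
        rhythmic = (fit.v1 != 0) | (fit.v2 != 0)
        assert rhythmic[:10].all()

    def test_objective_trace_non_decreasing(self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        for seed in range(3):
            fit = fit_once(m.values, s=4.0, seed=seed)
            diffs = np.diff(fit.objective_trace)
            assert np.all(diffs >= -1e-9)

    def test_same_seed_same_fit(self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        a = fit_once(m.values, s=3.0, seed=11)
        b = fit_once(m.values, s=3.0, seed=11)
        assert a.u1.tobytes() == b.u1.tobytes()
        assert a.v1.tobytes() == b.v1.tobytes()
        assert a.d == b.d

    def test_feasibility_invariants(self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        fit = fit_once(m.values, s=5.0, seed=1)
        fit.check_feasible()

    def test_s_out_of_range_rejected(self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        with pytest.raises(ValueError, match="feasible range"):
            fit_once(m.values, s=0.5)
        with pytest.raises(ValueError, match="feasible range"):
            fit_once(m.values, s=1000.0)


class TestCosinorEquivalence:
    def test_v_update_matches_least_squares_harmonics(self, rng):
        """With the cyclic components pinned to known, equally spaced times
        and no sparsity, the loading update is proportional to the
        least-squares cosinor (cos, sin) coefficients of each feature."""
        n, p = 48, 6
        t = np.arange(n) / n
        u1, u2 = np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        w1, w2 = X.T @ u1, X.T @ u2
        v1 = project_v(w1, np.sqrt(p))
        v2 = project_v(w2, np.sqrt(p))
        H = np.column_stack([np.ones(n), u1, u2])
        beta = np.linalg.lstsq(H, X, rcond=None)[0]
        bc, bs = beta[1], beta[2]
        np.testing.assert_allclose(v1, bc / np.linalg.norm(bc), atol=1e-8)
        np.testing.assert_allclose(v2, bs / np.linalg.norm(bs), atol=1e-8)


class TestFitMultistart:
    def test_single_restart_equals_fit_once_with_child_seed(
            self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        ms = fit_multistart(m.values, s=4.0, restarts=1, seed=9)
        child = int(np.random.default_rng(9).integers(0, 2**31 - 1, size=1)[0])
        once = fit_once(m.values, s=4.0, seed=child)
        assert ms.u1.tobytes() == once.u1.tobytes()
        assert ms.approx_error == once.approx_error

    def test_selected_fit_minimizes_approx_error(self, small_rhythmic):
        m = standardize(from_array(small_rhythmic.X))
        fit = fit_multistart(m.values, s=4.0, restarts=5, seed=2)
        errors = [r["approx_error"] for r in fit.restart_summary]
        assert fit.approx_error == min(errors)

    def test_noiseless_cross_term_negligible(self, noiseless_cycle):
        # with an exact rank-2 cyclic structure the reconstruction is
        # essentially perfect and the neglected cross term is negligible
        # against the data's total variation
        X, _, _ = noiseless_cycle
        fit = fit_multistart(X, s=np.sqrt(10), restarts=10, seed=5)
        total = float(np.sum(X * X))
        assert fit.approx_error / total < 1e-6
        assert abs(fit.cross_term) / total < 1e-6
        assert abs(fit.v1 @ fit.v2) < 0.01


def test_objective_and_error_are_consistent(rng):
    """2d(u1'Xv1+u2'Xv2) - d^2 N and the Frobenius error differ by
    ||X||_F^2 minus the cross term, by algebra; check numerically."""
    X = rng.normal(size=(15, 9))
    t = rng.uniform(size=15)
    u1, u2 = np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)
    v1 = rng.normal(size=9)
    v1 /= np.linalg.norm(v1)
    v2 = rng.normal(size=9)
    v2 /= np.linalg.norm(v2)
    d = 1.3
    obj = objective_value(X, u1, u2, v1, v2, d)
    err = approximation_error(X, u1, u2, v1, v2, d)
    cross = 2 * d * d * (u1 @ u2) * (v1 @ v2)
    direct = np.linalg.norm(
        X - d * np.outer(u1, v1) - d * np.outer(u2, v2), "fro") ** 2
    assert abs(err - direct) < 1e-8
    assert abs((np.sum(X * X) - obj + cross) - err) < 1e-8
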