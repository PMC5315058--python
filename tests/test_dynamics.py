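"""Forward integration, observation model, cubic reference and decay times."""

import numpy as np
import pytest
from scipy.linalg import expm

from structdyn.dynamics import (
    ConnectivityMatrix,
    CubicPolyParams,
    ObservationModel,
    StateTrajectory,
    cubic_poly_predict,
    decay_time,
    integrate_system,
    predict_observations,
    stability_check,
)
from structdyn.inputs import InputTrajectory


def grid_years(t_end=16.0, dt=0.1):
    return dt * np.arange(int(round(t_end / dt)) + 1)


class TestIntegrateSystem:
    def test_no_dynamics_gives_constant_states(self):
        g = grid_years()
        x0 = np.array([10.0, -3.0])
        traj = integrate_system(np.zeros((2, 2)), None, [], x0, g)
        np.testing.assert_allclose(traj.X, x0[:, None] * np.ones_like(g))

    def test_diagonal_decay_matches_exponential(self):
        g = grid_years(dt=0.01)
        a = -0.3
        traj = integrate_system(np.diag([a, a]), None, [], np.array([5.0, 2.0]), g)
        exact = np.array([5.0, 2.0])[:, None] * np.exp(a * g)[None, :]
        assert np.max(np.abs(traj.X - exact)) < 0.01

    def test_ten_percent_loss_in_5_3_years(self):
        # a = -0.02 loses 10% of volume in about 5.3 years
        g = grid_years(t_end=10.0)
        traj = integrate_system(np.array([[-0.02]]), None, [], np.array([100.0]), g)
        idx = int(round(5.3 / 0.1))
        assert traj.X[0, idx] == pytest.approx(90.0, abs=0.2)

    def test_euler_error_first_order_in_dt(self):
        A = np.array([[-0.4, 0.1], [0.1, -0.3]])
        x0 = np.array([3.0, -1.0])
        errs = []
        for dt in (0.2, 0.1, 0.05):
            g = grid_years(t_end=8.0, dt=dt)
            traj = integrate_system(A, None, [], x0, g)
            exact = np.stack([expm(A * t) @ x0 for t in g], axis=1)
            errs.append(np.max(np.abs(traj.X - exact)))
        for coarse, fine in zip(errs, errs[1:]):
            assert coarse / fine == pytest.approx(2.0, rel=0.25)

    def test_decay_time_agrees_with_simulation(self):
        a, dt = -0.015, 0.1
        g = grid_years(t_end=40.0, dt=dt)
        traj = integrate_system(np.array([[a]]), None, [], np.array([100.0]), g)
        t_sim = g[np.argmax(traj.X[0] <= 90.0)]
        assert abs(t_sim - decay_time(a, 10)) <= dt + 1e-9

    def test_bounded_with_stable_dynamics_and_bounded_input(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(5, 5))
        A = -(M @ M.T) / 20 - 0.01 * np.eye(5)  # negative definite
        g = grid_years(t_end=16.0)
        u = InputTrajectory(g, np.ones_like(g), "const")
        C = rng.normal(size=(5, 1))
        traj = integrate_system(A, C, [u], np.full(5, 50.0), g)
        assert np.all(np.isfinite(traj.X))
        assert np.max(np.abs(traj.X)) < 1e4

    def test_superposition_in_initial_state(self):
        A = np.array([[-0.1, 0.02], [0.02, -0.2]])
        g = grid_years()
        x1, x2 = np.array([1.0, 2.0]), np.array([-3.0, 0.5])
        t1 = integrate_system(A, None, [], x1, g).X
        t2 = integrate_system(A, None, [], x2, g).X
        t12 = integrate_system(A, None, [], x1 + x2, g).X
        np.testing.assert_allclose(t12, t1 + t2, atol=1e-9)

    def test_grid_mismatch_rejected(self):
        g = grid_years()
        u = InputTrajectory(g[:-5], np.ones(g.size - 5), "u")
        with pytest.raises(ValueError, match="grid"):
            integrate_system(np.zeros((1, 1)), np.ones((1, 1)), [u], np.array([1.0]), g)


class TestDecayTime:
    def test_printed_examples(self):
        assert decay_time(-0.005, 10) == pytest.approx(21.07, abs=0.01)
        assert decay_time(-0.02, 10) == pytest.approx(5.27, abs=0.01)

    def test_vanishing_loss_takes_no_time(self):
        assert decay_time(-0.01, 1e-9) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("a,L", [(0.0, 10), (0.01, 10), (-0.01, 0), (-0.01, 100)])
    def test_invalid_arguments_rejected(self, a, L):
        with pytest.raises(ValueError):
            decay_time(a, L)


class TestPredictObservations:
    def make_traj(self):
        g = grid_years()
        X = np.vstack([np.full_like(g, 7.0), g])
        return StateTrajectory(time_grid=g, X=X, x0=X[:, 0])

    def test_zero_confounds_equal_sampled_states(self):
        traj = self.make_traj()
        pred = predict_observations(traj, np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(pred[:, 0], 7.0)
        np.testing.assert_allclose(pred[:, 1], [0.0, 5.0, 10.0], atol=1e-9)

    def test_site_indicator_shifts_predictions(self):
        traj = self.make_traj()
        ages = np.array([2.0, 4.0])
        obs = ObservationModel(
            confound_matrix=np.array([[0.0], [1.0]]),
            b0=np.array([[3.0, 3.0]]),
        )
        pred = predict_observations(traj, ages, obs)
        base = predict_observations(traj, ages)
        np.testing.assert_allclose(pred[0], base[0])
        np.testing.assert_allclose(pred[1], base[1] + 3.0)

    def test_linear_in_confound_coefficients(self):
        traj = self.make_traj()
        ages = np.array([1.0, 2.0, 3.0])
        X0 = np.array([[1.0], [2.0], [0.5]])
        b1 = np.array([[1.0, -1.0]])
        p0 = predict_observations(traj, ages)
        p1 = predict_observations(traj, ages, ObservationModel(X0, b1))
        p2 = predict_observations(traj, ages, ObservationModel(X0, 2 * b1))
        np.testing.assert_allclose(p2 - p0, 2 * (p1 - p0), atol=1e-12)

    def test_out_of_range_age_names_the_scan(self):
        traj = self.make_traj()
        with pytest.raises(ValueError, match="scan 1"):
            predict_observations(traj, np.array([2.0, 99.0]))


class TestCubicPoly:
    @pytest.mark.parametrize("row,t,expected", [
        ((5.0, 0, 0, 0), 2.0, 5.0),
        ((0, 1.0, 0, 0), 2.0, 2.0),
        ((0, 0, 0, 1.0), 3.0, 27.0),
    ])
    def test_single_coefficient_rows(self, row, t, expected):
        pred = cubic_poly_predict(np.array([t]), CubicPolyParams(np.array([row])))
        assert pred[0, 0] == pytest.approx(expected)

    def test_regions_independent(self):
        B = np.array([[1.0, 0, 0, 0], [0, 2.0, 0, 0]])
        pred = cubic_poly_predict(np.array([1.0, 3.0]), CubicPolyParams(B))
        np.testing.assert_allclose(pred, [[1.0, 2.0], [1.0, 6.0]])


class TestStability:
    def test_uniform_decay_is_stable(self):
        absc, stable = stability_check(-0.02 * np.eye(3))
        assert absc == pytest.approx(-0.02)
        assert stable

    def test_positive_self_connections_unstable(self):
        # growth without bound: |1 + dt*lambda| > 1
        _, stable = stability_check(0.1 * np.eye(3), dt=0.1)
        assert not stable

    def test_random_symmetric_negative_definite_stable(self, rng):
        M = rng.normal(size=(6, 6))
        A = -(M @ M.T) / 100 - 0.001 * np.eye(6)
        absc, stable = stability_check(A)
        assert absc < 0
        assert stable

    def test_symmetric_flag_validated(self):
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(np.array([[-1.0, 0.5], [0.2, -1.0]]), symmetric=True)
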