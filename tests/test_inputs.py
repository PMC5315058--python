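"""Developmental input functions: sigmoid puberty curve, alpha and Gaussian growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structdyn.inputs import (
    AlphaGrowthParams,
    GaussianGrowthParams,
    SigmoidParams,
    alpha_growth,
    alpha_growth_closed_form,
    fit_sigmoid,
    gaussian_growth,
    puberty_input,
    rescale_puberty_scores,
    sigmoid_transition,
)


class TestSigmoidTransition:
    @pytest.mark.parametrize("p1,p2", [(12.66, 0.21), (14.34, 0.22), (10.0, 1.0)])
    def test_half_maximum_at_inflection(self, p1, p2):
        assert sigmoid_transition(p1, SigmoidParams(p1, p2)) == pytest.approx(0.5)

    def test_unit_exponent_value(self):
        # at t = p1 - 1/p2 the base-10 exponent is exactly 1 -> 1/11
        p = SigmoidParams(13.0, 0.25)
        assert sigmoid_transition(13.0 - 4.0, p) == pytest.approx(1.0 / 11.0)

    def test_direct_formula_evaluation(self):
        # frozen from 1/(1 + 10**((12.66 - 20) * 0.21)) with the girls' curve
        p = SigmoidParams(12.66, 0.21)
        assert sigmoid_transition(20.0, p) == pytest.approx(0.9720558303352026, rel=1e-12)

    def test_monotone_increasing_with_limits(self):
        p = SigmoidParams(12.0, 0.3)
        t = np.linspace(-20, 45, 500)  # inside float-saturation limits
        h = sigmoid_transition(t, p)
        assert np.all(np.diff(h) > 0)
        assert h[0] < 1e-6 and h[-1] > 1 - 1e-6

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(12.0, 0.0)
        with pytest.raises(ValueError):
            SigmoidParams(12.0, -0.1)


class TestPubertyInput:
    def test_peak_at_inflection_age(self):
        p = SigmoidParams(14.34, 0.22)
        grid = np.arange(6.0, 22.0005, 0.001)
        u = puberty_input(grid, p)
        assert grid[np.argmax(u.values)] == pytest.approx(14.34, abs=1e-9)

    def test_peak_value_is_log10_slope_quarter(self):
        p = SigmoidParams(12.0, 0.3)
        u = puberty_input(np.array([11.0, 12.0, 13.0]), p)
        assert u.values[1] == pytest.approx(math.log(10) * 0.3 / 4)

    @given(s=st.floats(0.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_about_inflection(self, s):
        p = SigmoidParams(13.0, 0.2)
        left = puberty_input(np.array([13.0 - s, 13.0]), p).values[0]
        right = puberty_input(np.array([13.0, 13.0 + s]), p).values[1]
        assert left == pytest.approx(right, rel=1e-12)

    def test_integrates_to_sigmoid_increment(self):
        p = SigmoidParams(13.0, 0.25)
        grid = np.arange(-20.0, 46.0, 0.01)
        u = puberty_input(grid, p)
        area = np.trapezoid(u.values, grid)
        expected = sigmoid_transition(grid[-1], p) - sigmoid_transition(grid[0], p)
        assert area == pytest.approx(expected, abs=1e-6)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            puberty_input(np.array([]), SigmoidParams(13.0, 0.2))


class TestFitSigmoid:
    def test_noise_free_recovery(self):
        p = SigmoidParams(13.0, 0.2)
        ages = np.linspace(6, 22, 60)
        fit = fit_sigmoid(ages, sigmoid_transition(ages, p))
        assert fit.params.p1 == pytest.approx(13.0, rel=1e-6)
        assert fit.params.p2 == pytest.approx(0.2, rel=1e-6)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fit_sigmoid(np.linspace(6, 22, 20), np.full(20, 0.5))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_sigmoid(np.arange(5.0), np.linspace(0, 1, 5))

    def test_monte_carlo_recovery_within_three_se(self, rng):
        """100 replicates at n=400, noise sd 0.1: mean estimate within 3 MC SEs."""
        p = SigmoidParams(13.0, 0.2)
        p1s, p2s = [], []
        for _ in range(100):
            ages = rng.uniform(6, 22, 400)
            # unclipped noise: clipping censors the extremes and biases the slope
            scores = sigmoid_transition(ages, p) + rng.normal(0, 0.1, 400)
            fit = fit_sigmoid(ages, scores)
            p1s.append(fit.params.p1)
            p2s.append(fit.params.p2)
        for est, true in ((np.array(p1s), 13.0), (np.array(p2s), 0.2)):
            se = est.std(ddof=1) / math.sqrt(len(est))
            assert abs(est.mean() - true) < 3 * se + 1e-12

    def test_raw_stage_rescaling(self):
        assert rescale_puberty_scores([1.0, 2.5, 4.0]) == pytest.approx([0, 0.5, 1.0])


class TestAlphaGrowth:
    def test_unit_value_at_onset(self):
        grid = np.arange(6.0, 22.0, 0.1)
        u = alpha_growth(grid, AlphaGrowthParams(tau=2.0, onset_age=6.0))
        assert u.values[0] == 1.0

    def test_zero_before_onset(self):
        grid = np.arange(3.0, 22.0, 0.1)
        u = alpha_growth(grid, AlphaGrowthParams(tau=2.0, onset_age=6.0))
        assert np.all(u.values[grid < 6.0 - 1e-9] == 0.0)

    @pytest.mark.parametrize("tau", [1.0, 2.0, 4.0])
    def test_peak_near_critically_damped_optimum(self, tau):
        """Peak at onset + (20/21) tau, within two grid steps of the closed form."""
        dt = 0.1
        grid = np.arange(0.0, 30.0, dt)
        u = alpha_growth(grid, AlphaGrowthParams(tau=tau, onset_age=0.0))
        t_peak = grid[np.argmax(u.values)]
        assert abs(t_peak - 20.0 / 21.0 * tau) <= 2 * dt + 1e-12

    def test_matches_closed_form(self):
        dt = 0.01
        grid = np.arange(0.0, 20.0, dt)
        u = alpha_growth(grid, AlphaGrowthParams(tau=2.0, onset_age=0.0))
        exact = alpha_growth_closed_form(grid, tau=2.0)
        assert np.max(np.abs(u.values - exact)) < 0.05

    def test_time_scale_invariance(self):
        """u2(t; tau) == u2(k t; k tau) exactly on matching Euler grids."""
        k = 3.0
        grid = np.arange(0.0, 10.0, 0.05)
        u1 = alpha_growth(grid, AlphaGrowthParams(tau=1.5, onset_age=0.0))
        u2 = alpha_growth(grid * k, AlphaGrowthParams(tau=1.5 * k, onset_age=0.0))
        np.testing.assert_allclose(u1.values, u2.values, rtol=1e-12)

    @given(tau=st.floats(0.5, 8.0))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative_and_unimodal(self, tau):
        grid = np.arange(0.0, 40.0, 0.05)
        u = alpha_growth(grid, AlphaGrowthParams(tau=tau, onset_age=0.0)).values
        assert np.all(u >= 0)
        d = np.diff(u)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
        assert sign_changes <= 1

    def test_euler_first_order_convergence(self):
        errs = []
        for dt in (0.1, 0.05, 0.025):
            grid = np.arange(0.0, 16.0, dt)
            u = alpha_growth(grid, AlphaGrowthParams(tau=2.0, onset_age=0.0))
            errs.append(np.max(np.abs(u.values - alpha_growth_closed_form(grid, 2.0))))
        for e_coarse, e_fine in zip(errs, errs[1:]):
            assert e_coarse / e_fine == pytest.approx(2.0, rel=0.2)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            AlphaGrowthParams(tau=0.0)


class TestGaussianGrowth:
    def test_peak_and_one_sigma_values(self):
        p = GaussianGrowthParams(m_g=7.5, sigma=2.0)
        grid = np.array([5.5, 7.5, 9.5])
        u = gaussian_growth(grid, p).values
        assert u[1] == pytest.approx(1.0)
        assert u[0] == pytest.approx(math.exp(-0.5))
        assert u[2] == pytest.approx(math.exp(-0.5))
        assert u[0] == pytest.approx(u[2])  # symmetry about the mean

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianGrowthParams(m_g=7.0, sigma=-1.0)
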