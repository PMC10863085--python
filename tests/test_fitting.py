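import math

import numpy as np
import pytest

from growthfit import (
    LogTrace,
    ModelParams,
    fit_easy_linear,
    fit_manual,
    fit_parametric,
    model_population,
    model_y,
)
from growthfit.errors import (
    DataError,
    NonIdentifiableError,
    ParameterError,
    SelectionError,
)
from .conftest import random_sigmoid_params, sigmoid_trace


def brute_force_easy_linear(trace, window):
    """Independent enumeration oracle: polyfit over every valid subsegment."""
    best = None
    valid = np.nonzero(trace.valid_mask)[0]
    for k in range(len(valid) - window + 1):
        idx = valid[k : k + window]
        if idx[-1] - idx[0] != window - 1:  # masked gap inside
            continue
        slope = np.polyfit(trace.times[idx], trace.y[idx], 1)[0]
        if best is None or slope > best[0]:
            best = (slope, int(idx[0]), int(idx[-1]))
    return best


class TestFitParametric:
    @pytest.mark.parametrize("model", ["logistic", "gompertz"])
    def test_noise_free_recovery(self, model):
        truth = ModelParams(model, 2.0, 0.8, 10.0, n0=0.05)
        trace = sigmoid_trace(truth, t_max=40.0, step=0.25)
        fit = fit_parametric(trace, model)
        assert fit.converged
        assert fit.params.a == pytest.approx(truth.a, rel=1e-4)
        assert fit.params.mu_max == pytest.approx(truth.mu_max, rel=1e-4)
        assert fit.params.lam == pytest.approx(truth.lam, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_standard_errors_near_zero_on_exact_data(self):
        truth = ModelParams("logistic", 2.0, 0.8, 10.0, n0=0.05)
        fit = fit_parametric(sigmoid_trace(truth, t_max=40.0), "logistic")
        assert all(0 <= fit.se[k] < 1e-6 for k in ("a", "mu_max", "lam"))

    def test_window_brackets_the_exponential_phase(self):
        truth = ModelParams("logistic", 2.0, 0.8, 10.0, n0=0.05)
        trace = sigmoid_trace(truth, t_max=40.0, step=0.25)
        fit = fit_parametric(trace, "logistic")
        i, j = fit.window
        assert trace.times[i] == pytest.approx(10.0, abs=0.25)
        assert trace.times[j] == pytest.approx(10.0 + 2.0 / 0.8, abs=0.25)

    def test_flat_trace_not_identifiable(self):
        trace = LogTrace(np.arange(10.0), np.zeros(10), 0.1)
        with pytest.raises(NonIdentifiableError):
            fit_parametric(trace, "logistic")

    def test_too_few_points(self):
        trace = LogTrace(np.arange(4.0), np.arange(4.0) * 0.5, 0.1)
        with pytest.raises(DataError):
            fit_parametric(trace, "gompertz")

    def test_local_optimality_against_random_probes(self, rng):
        """No random probe parameter vector beats the optimizer's residual."""
        truth = random_sigmoid_params(rng, "gompertz", mu_floor=0.3, lam_max=10.0)
        trace = sigmoid_trace(truth, noise_sd=0.01, rng=rng)
        fit = fit_parametric(trace, "gompertz")
        t, y = trace.times[trace.valid_mask], trace.y[trace.valid_mask]
        best = np.sum((model_y(fit.params, t) - y) ** 2)
        for _ in range(50):
            probe = random_sigmoid_params(rng, "gompertz", mu_floor=0.3, lam_max=10.0)
            assert best <= np.sum((model_y(probe, t) - y) ** 2) + 1e-12


class TestFitEasyLinear:
    def test_globally_linear_trace(self, linear_trace):
        fit = fit_easy_linear(linear_trace, 5)
        assert fit.mu_max == pytest.approx(0.5, abs=1e-12)
        assert fit.window == (0, 4)  # earliest of the all-tied windows

    def test_window_spanning_whole_trace(self, linear_trace):
        n = len(linear_trace.times)
        fit = fit_easy_linear(linear_trace, n)
        assert fit.window == (0, n - 1)

    def test_piecewise_trace_winning_segment(self, piecewise_trace):
        fit = fit_easy_linear(piecewise_trace, 5)
        assert fit.mu_max == pytest.approx(1.0, abs=1e-12)
        t_lo = piecewise_trace.times[fit.window[0]]
        t_hi = piecewise_trace.times[fit.window[1]]
        assert 5.0 <= t_lo < t_hi <= 10.0
        # all slope-1 windows tie exactly; the oracle must agree on the slope
        # (window identity under exact ties is float-fragile across formulas)
        oracle = brute_force_easy_linear(piecewise_trace, 5)
        assert fit.mu_max == pytest.approx(oracle[0], abs=1e-9)

    def test_equals_brute_force_on_noisy_sigmoids(self, rng):
        for _ in range(10):
            p = random_sigmoid_params(rng, "logistic", mu_floor=0.3, lam_max=10.0)
            trace = sigmoid_trace(p, step=0.5, noise_sd=0.01, rng=rng)
            fit = fit_easy_linear(trace, 8)
            slope, i, j = brute_force_easy_linear(trace, 8)
            assert fit.window == (i, j)
            assert fit.mu_max == pytest.approx(slope, rel=1e-9)

    def test_masked_gap_breaks_contiguity(self):
        t = np.arange(10.0)
        y = 0.5 * t
        mask = np.ones(10, bool)
        mask[4] = False
        trace = LogTrace(t, np.where(mask, y, np.nan), 0.1, valid_mask=mask)
        fit = fit_easy_linear(trace, 5)
        assert fit.window == (5, 9)  # only the right-hand run has 5 contiguous points

    def test_mu_non_increasing_in_window_size_on_sigmoid(self):
        truth = ModelParams("logistic", 2.0, 0.8, 10.0, n0=0.05)
        trace = sigmoid_trace(truth, t_max=40.0, step=0.5)
        mus = [fit_easy_linear(trace, w).mu_max for w in (4, 8, 16, 32)]
        assert all(a >= b - 1e-12 for a, b in zip(mus, mus[1:]))

    def test_window_below_two_rejected(self, linear_trace):
        with pytest.raises(ParameterError):
            fit_easy_linear(linear_trace, 1)

    def test_no_long_enough_run(self):
        trace = LogTrace(np.arange(3.0), np.arange(3.0), 0.1)
        with pytest.raises(DataError):
            fit_easy_linear(trace, 5)


class TestFitManual:
    def test_pure_exponential_selection(self, linear_trace):
        fit = fit_manual(linear_trace, 2.0, 8.0)
        assert fit.mu_max == pytest.approx(0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_piecewise_selection_matches_closed_form(self, piecewise_trace):
        fit = fit_manual(piecewise_trace, 5.0, 10.0)
        assert fit.mu_max == pytest.approx(1.0, abs=1e-12)
        assert piecewise_trace.times[fit.window[0]] == 5.0
        assert piecewise_trace.times[fit.window[1]] == 10.0

    def test_single_point_selection_rejected(self, linear_trace):
        with pytest.raises(SelectionError):
            fit_manual(linear_trace, 1.9, 2.1)

    def test_reversed_window_rejected(self, linear_trace):
        with pytest.raises(ParameterError):
            fit_manual(linear_trace, 5.0, 2.0)

    def test_reproduces_easy_linear_slope_on_winning_window(self, rng):
        p = random_sigmoid_params(rng, "gompertz", mu_floor=0.3, lam_max=10.0)
        trace = sigmoid_trace(p, step=0.5, noise_sd=0.005, rng=rng)
        el = fit_easy_linear(trace, 10)
        manual = fit_manual(trace, trace.times[el.window[0]], trace.times[el.window[1]])
        assert manual.mu_max == pytest.approx(el.mu_max, rel=1e-12)
        assert manual.window == el.window
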