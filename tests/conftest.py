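import numpy as np
import pytest

from growthfit import LogTrace, ModelParams, model_population, log_transform


def random_sigmoid_params(rng, model, mu_floor=0.1, lam_max=50.0):
    """A well-conditioned random parameter set for landmark/fit checks."""
    return ModelParams(
        model=model,
        a=float(rng.uniform(0.5, 4.0)),
        mu_max=float(rng.uniform(mu_floor, 2.0)),
        lam=float(rng.uniform(0.0, lam_max)),
        n0=float(rng.uniform(0.01, 0.5)),
    )


def sigmoid_trace(params, t_max=None, step=0.25, noise_sd=0.0, rng=None):
    """Log-transformed trace of a sigmoid curve, optionally noisy."""
    if t_max is None:
        t_max = params.lam + 4.0 * params.a / params.mu_max
    t = np.arange(0.0, t_max + step / 2, step)
    values = model_population(params, t)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return log_transform(values, t)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def linear_trace():
    """y = 0.5 t exactly: an ideal exponential in log space."""
    t = np.arange(0.0, 10.5, 0.5)
    return LogTrace(times=t, y=0.5 * t, n0=0.1)


@pytest.fixture
def piecewise_trace():
    """Flat, then slope 1 on t in [5, 10], then flat — a clean growth phase."""
    t = np.arange(0.0, 15.5, 0.5)
    y = np.where(t < 5, 0.0, np.where(t <= 10, t - 5.0, 5.0))
    return LogTrace(times=t, y=y, n0=0.05)
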