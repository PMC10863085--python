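"""Sigmoid growth models in the Zwietering parameterization.

The models describe logarithmic population size ``y = ln(N/N0)`` as a function
of time. Both sigmoids are parameterized directly in terms of the quantities a
microbiologist reports:

* ``A`` — asymptotic value of ``y``; the plateau population is ``N0 * exp(A)``,
* ``mu_max`` — maximum specific growth rate (h^-1), the slope of ``y`` at the
  inflection point,
* ``lam`` — lag time (h), the x-intercept of the tangent at the inflection.

Modified logistic::

    y(t) = A / (1 + exp(4 mu_max / A * (lam - t) + 2))

Modified Gompertz::

    y(t) = A * exp(-exp(mu_max * e / A * (lam - t) + 1))

The exponential model is ``N = N0 * exp(mu_max * t)``, i.e. ``y = mu_max * t``;
it has no lag or plateau and therefore no phase landmarks.

Two conventions for the exponential-phase boundaries are supported:

* ``standard`` — the tangent construction: the phase starts at ``lam`` (where
  the inflection tangent crosses y = 0) and ends where that tangent reaches
  ``y = A``, i.e. at ``lam + A / mu_max``.
* ``tight`` — the curvature construction: the phase starts at the smallest and
  ends at the largest zero of the third derivative of ``y``; this interval is
  strictly inside the standard one and tracks the visually linear segment of
  the sigmoid more closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError, ParameterError, UnsupportedModelError

__all__ = [
    "ModelParams",
    "SIGMOID_MODELS",
    "model_y",
    "model_population",
    "inflection_time",
    "lag_time",
    "exp_phase_bounds",
]

SIGMOID_MODELS = ("logistic", "gompertz")
_MODELS = SIGMOID_MODELS + ("exponential",)


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of a growth model.

    Parameters
    ----------
    model:
        One of ``"logistic"``, ``"gompertz"``, ``"exponential"``.
    a:
        Asymptotic log-population ``ln(N_inf/N0)`` (dimensionless, > 0).
        Unused by the exponential model.
    mu_max:
        Maximum specific growth rate in h^-1 (> 0).
    lam:
        Lag time in hours. Unused by the exponential model.
    n0:
        Reference population size N0 in population units (e.g. OD600), used
        to map ``y`` back to population size: ``N = n0 * exp(y)``.
    """

    model: str
    a: float | None
    mu_max: float
    lam: float | None
    n0: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ParameterError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if not (self.mu_max > 0) or not math.isfinite(self.mu_max):
            raise ParameterError(f"mu_max must be finite and > 0, got {self.mu_max}")
        if self.model in SIGMOID_MODELS:
            if self.a is None or not (self.a > 0) or not math.isfinite(self.a):
                raise ParameterError(f"A must be finite and > 0 for sigmoid models, got {self.a}")
            if self.lam is None or not math.isfinite(self.lam):
                raise ParameterError(f"lam must be finite for sigmoid models, got {self.lam}")
        if self.n0 is not None and not (self.n0 > 0):
            raise ParameterError(f"n0 must be > 0, got {self.n0}")

    @property
    def n_inf(self) -> float:
        """Plateau population size ``N0 * exp(A)`` (sigmoid models only)."""
        if self.model not in SIGMOID_MODELS:
            raise UnsupportedModelError("the exponential model has no plateau")
        return self.n0 * math.exp(self.a)


def _require_sigmoid(p: ModelParams, what: str) -> None:
    if p.model not in SIGMOID_MODELS:
        raise UnsupportedModelError(f"{what} is undefined for the {p.model} model")


def model_y(p: ModelParams, t):
    """Evaluate ``y(t) = ln(N(t)/N0)`` for the model, vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    if p.model == "exponential":
        return p.mu_max * t
    with np.errstate(over="ignore"):
        if p.model == "logistic":
            return p.a / (1.0 + np.exp(4.0 * p.mu_max / p.a * (p.lam - t) + 2.0))
        # gompertz
        return p.a * np.exp(-np.exp(p.mu_max * math.e / p.a * (p.lam - t) + 1.0))


def model_population(p: ModelParams, t):
    """Population size ``N(t) = n0 * exp(y(t))`` in population units."""
    return p.n0 * np.exp(model_y(p, t))


def inflection_time(p: ModelParams) -> float:
    """Time of maximum slope of ``y``; the slope there equals ``mu_max``.

    Logistic: ``lam + A/(2 mu_max)`` (where y = A/2);
    Gompertz: ``lam + A/(e mu_max)`` (where y = A/e).
    """
    _require_sigmoid(p, "inflection time")
    if p.model == "logistic":
        return p.lam + p.a / (2.0 * p.mu_max)
    return p.lam + p.a / (math.e * p.mu_max)


def _d3_logistic(p: ModelParams, t):
    # y = A*sigma(s), s = k(t-lam) - 2, k = 4 mu/A
    # sigma''' = sigma(1-sigma)(1 - 6 sigma + 6 sigma^2)
    k = 4.0 * p.mu_max / p.a
    s = k * (np.asarray(t, dtype=float) - p.lam) - 2.0
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(-s))
    return p.a * k**3 * sig * (1.0 - sig) * (1.0 - 6.0 * sig + 6.0 * sig**2)


def _d3_gompertz(p: ModelParams, t):
    # y = A*g(u), u = c(t-lam) - 1, c = e mu/A, g(u) = exp(-exp(-u))
    # g''' = g * v * (v^2 - 3v + 1), v = exp(-u)
    c = math.e * p.mu_max / p.a
    u = c * (np.asarray(t, dtype=float) - p.lam) - 1.0
    with np.errstate(over="ignore", under="ignore"):
        v = np.exp(-u)
        g = np.exp(-v)
        out = p.a * c**3 * g * v * (v**2 - 3.0 * v + 1.0)
    return np.where(np.isfinite(out), out, 0.0)


def third_derivative(p: ModelParams, t):
    """d^3y/dt^3 of the sigmoid model, vectorized over ``t``."""
    _require_sigmoid(p, "third derivative")
    if p.model == "logistic":
        return _d3_logistic(p, t)
    return _d3_gompertz(p, t)


def _third_derivative_zeros(p: ModelParams) -> list[float]:
    """All sign-change zeros of d^3y/dt^3 on [lam - A/mu, lam + 3A/mu].

    Sign-change bracketing on a fine grid followed by Brent root refinement
    to 1e-10 h. Both sigmoids have exactly two such zeros, flanking the
    inflection point.
    """
    span = p.a / p.mu_max
    lo, hi = p.lam - span, p.lam + 3.0 * span
    grid = np.linspace(lo, hi, 4001)
    vals = third_derivative(p, grid)
    roots: list[float] = []
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        r = brentq(lambda t: float(third_derivative(p, t)), grid[i], grid[i + 1], xtol=1e-10)
        roots.append(float(r))
    # grid nodes landing exactly on a zero
    for i in np.nonzero(sign == 0)[0]:
        roots.append(float(grid[i]))
    if len(roots) < 2:
        raise NumericalError(
            f"could not bracket two third-derivative zeros for {p.model} "
            f"(A={p.a}, mu_max={p.mu_max}, lam={p.lam}); found {len(roots)}"
        )
    return sorted(roots)


def lag_time(p: ModelParams, definition: str = "standard") -> float:
    """Lag time under the requested definition.

    ``standard`` — x-intercept of the tangent at the inflection point; in this
    parameterization that is the parameter ``lam`` itself.
    ``tight`` — the smallest zero of the third derivative of ``y``, i.e. the
    time of the steepest increase in slope; always later than ``standard``.
    """
    _require_sigmoid(p, "lag time")
    if definition == "standard":
        return float(p.lam)
    if definition == "tight":
        return _third_derivative_zeros(p)[0]
    raise ParameterError(f"unknown lag definition {definition!r}")


def exp_phase_bounds(p: ModelParams, definition: str = "standard") -> tuple[float, float]:
    """(start, end) of the exponential growth phase in hours.

    The start is :func:`lag_time` under the same definition. The standard end
    is where the inflection tangent reaches ``y = A``, i.e. ``lam + A/mu_max``
    for both sigmoids; the tight end is the largest zero of the third
    derivative.
    """
    _require_sigmoid(p, "exponential phase")
    if definition == "standard":
        return float(p.lam), float(p.lam + p.a / p.mu_max)
    if definition == "tight":
        zeros = _third_derivative_zeros(p)
        return zeros[0], zeros[-1]
    raise ParameterError(f"unknown phase definition {definition!r}")
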