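"""Synthetic-curve validation of the parametric fitters.

The study: draw growth parameters from uniform distributions spanning
biologically plausible microbial ranges, render exact Logistic or Gompertz
curves in population space, optionally add Gaussian measurement noise, push
each curve through the package's own preprocessing and nonlinear fit with
its generating model, and summarize per-parameter recovery as the median
over curves of the relative error |estimate - truth| / |truth|.

Default parameter ranges: N0 ~ U(0, 0.5), A ~ U(0.5, 4), mu_max ~ U(0, 2)
(h^-1), lambda ~ U(0, 100) (h). Draws of N0 or mu_max below 1e-3 are redrawn
to avoid numerically degenerate curves. The default time grid is 0-200 h in
0.5 h steps so that even late, slow growers reach saturation within the
observation window; curves whose standard exponential phase still extends
past the grid are fitted anyway and flagged.

Noise is additive in population space (sd in population units, default 0.01),
emulating instrument noise on optical density readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationRunError
from .fitting import fit_parametric
from .growth_models import ModelParams, SIGMOID_MODELS, model_population
from .preprocess import log_transform, rolling_smooth

__all__ = [
    "SyntheticSpec",
    "ValidationReport",
    "DEFAULT_PARAM_RANGES",
    "sample_parameters",
    "generate_curve",
    "run_validation",
]

DEFAULT_PARAM_RANGES = {
    "n0": (0.0, 0.5),
    "a": (0.5, 4.0),
    "mu_max": (0.0, 2.0),
    "lam": (0.0, 100.0),
}

#: redraw below this to avoid degenerate (flat or invisible) curves
DEGENERACY_FLOOR = 1e-3

VALIDATED_PARAMS = ("a", "mu_max", "lam")


def _default_grid() -> np.ndarray:
    return np.arange(0.0, 200.0 + 0.25, 0.5)


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic validation study."""

    model: str
    n_curves: int = 100
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    noise_sd: float = 0.01
    time_grid: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0
    smooth_window: int = 1  # 1 = no smoothing

    def __post_init__(self) -> None:
        if self.model not in SIGMOID_MODELS:
            raise ParameterError(f"model must be one of {SIGMOID_MODELS}, got {self.model!r}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if len(self.time_grid) > 1 and not np.all(np.diff(self.time_grid) > 0):
            raise ParameterError("time_grid must be strictly increasing")


@dataclass
class ValidationReport:
    """Median relative recovery errors of one study.

    ``median_relative_error`` maps parameter name (a, mu_max, lam) to the
    median over converged fits of |estimate - truth| / |truth|.
    """

    model: str
    n_curves: int
    n_converged: int
    n_unsaturated: int  # curves whose standard phase end lies beyond the grid
    noise_sd: float
    median_relative_error: dict = field(default_factory=dict)

    @property
    def max_median_error(self) -> float:
        return max(self.median_relative_error.values())


def sample_parameters(spec: SyntheticSpec, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter set uniformly from the configured ranges.

    N0 and mu_max draws below the degeneracy floor (1e-3) are redrawn.
    """
    def draw(name, floor=None):
        lo, hi = spec.param_ranges[name]
        while True:
            v = float(rng.uniform(lo, hi))
            if floor is None or v >= floor:
                return v

    return ModelParams(
        model=spec.model,
        n0=draw("n0", DEGENERACY_FLOOR),
        a=draw("a"),
        mu_max=draw("mu_max", DEGENERACY_FLOOR),
        lam=draw("lam"),
    )


def generate_curve(p: ModelParams, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Render the curve in population units on the grid, plus Gaussian noise."""
    values = model_population(p, spec.time_grid)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=len(values))
    return values


def run_validation(spec: SyntheticSpec) -> ValidationReport:
    """Run the full generate / preprocess / fit / score study.

    Each synthetic curve is log-transformed exactly as measured data would be
    (the true N0 is not revealed to the fitter) and fitted with its
    generating model. Relative errors are recorded per parameter over
    converged fits only. More than 50% non-convergence aborts the study.
    """
    if spec.n_curves < 10:
        raise ParameterError(f"need at least 10 curves for a meaningful study, got {spec.n_curves}")
    rng = np.random.default_rng(spec.seed)
    errors = {name: [] for name in VALIDATED_PARAMS}
    n_converged = 0
    n_unsaturated = 0
    grid_end = float(spec.time_grid[-1])
    for _ in range(spec.n_curves):
        truth = sample_parameters(spec, rng)
        values = generate_curve(truth, spec, rng)
        if truth.lam + truth.a / truth.mu_max > grid_end:
            n_unsaturated += 1
        if spec.smooth_window > 1:
            values = rolling_smooth(values, spec.smooth_window)
        trace = log_transform(values, spec.time_grid)
        fit = fit_parametric(trace, spec.model)
        if not fit.converged or fit.params is None:
            continue
        n_converged += 1
        est = fit.params
        for name in VALIDATED_PARAMS:
            true_v = getattr(truth, name)
            errors[name].append(abs(getattr(est, name) - true_v) / abs(true_v))
    if n_converged < spec.n_curves / 2:
        raise ValidationRunError(
            f"only {n_converged}/{spec.n_curves} fits converged; study not interpretable"
        )
    medians = {name: float(np.median(vals)) for name, vals in errors.items()}
    return ValidationReport(
        model=spec.model,
        n_curves=spec.n_curves,
        n_converged=n_converged,
        n_unsaturated=n_unsaturated,
        noise_sd=spec.noise_sd,
        median_relative_error=medians,
    )
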