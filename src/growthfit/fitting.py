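"""Growth-rate estimation: parametric sigmoid fits, Easy Linear, manual.

Three routes from a log-transformed trace to a maximum specific growth rate:

* :func:`fit_parametric` — nonlinear least squares of the modified Logistic
  or Gompertz model to the entire curve; yields A, mu_max and lam with
  standard errors, plus the exponential-phase window implied by the model.
* :func:`fit_easy_linear` — the sliding-window heuristic: an ordinary
  least-squares line through every contiguous subsegment of a fixed number
  of points; the maximum slope is mu_max and the winning subsegment marks
  the exponential phase.
* :func:`fit_manual` — a straight-line fit over a user-chosen time window,
  for curves no automatic method captures.

All three operate on valid points only; masked points break subsegment
contiguity so a sliding window never spans a gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, NonIdentifiableError, ParameterError, SelectionError
from .growth_models import ModelParams, SIGMOID_MODELS, exp_phase_bounds, model_y
from .preprocess import LogTrace

__all__ = ["FitResult", "fit_parametric", "fit_easy_linear", "fit_manual", "DEFAULT_WINDOW"]

#: default Easy Linear subsegment size in data points
DEFAULT_WINDOW = 10


@dataclass
class FitResult:
    """Outcome of one growth-rate estimation.

    ``params`` carries the full sigmoid parameter set for parametric fits;
    window methods estimate only the slope, exposed as ``mu_max`` (which may
    be non-positive for declining traces). ``window`` holds the inclusive
    (start, end) data indices of the exponential segment when one is defined.
    A failed optimization is reported via ``converged=False``, not an
    exception, so whole plates can be fitted in one pass.
    """

    method: str
    mu_max: float
    params: ModelParams | None = None
    se: dict = field(default_factory=dict)
    r_squared: float = math.nan
    window: tuple[int, int] | None = None
    converged: bool = True
    intercept: float = math.nan

    def __post_init__(self) -> None:
        if self.window is not None:
            start, end = self.window
            if not start < end:
                raise ParameterError(f"window indices must satisfy start < end, got {self.window}")


def _valid_points(trace: LogTrace):
    mask = trace.valid_mask
    return trace.times[mask], trace.y[mask], np.nonzero(mask)[0]


def _ols(t: np.ndarray, y: np.ndarray):
    """Least-squares line fit; returns slope, intercept, r^2, se(slope)."""
    n = len(t)
    tm, ym = t.mean(), y.mean()
    stt = np.sum((t - tm) ** 2)
    slope = np.sum((t - tm) * (y - ym)) / stt
    intercept = ym - slope * tm
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    se = math.sqrt(ss_res / (n - 2) / stt) if n > 2 else math.nan
    return float(slope), float(intercept), r2, se


def _initial_guess(t: np.ndarray, y: np.ndarray):
    """Robust starting point for sigmoid fits on sigmoid-like data."""
    a0 = float(np.max(y))
    mid = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    if len(mid) and np.max(mid) > 0:
        i = int(np.argmax(mid)) + 1
        mu0 = float(np.max(mid))
        lam0 = float(t[i] - y[i] / mu0)
    else:
        mu0 = a0 / (t[-1] - t[0])
        lam0 = float(t[0])
    lam0 = max(lam0, 0.0)
    return a0, mu0, lam0


def fit_parametric(trace: LogTrace, model: str) -> FitResult:
    """Fit a sigmoid growth model to the whole trace by least squares.

    Minimizes the sum of squared residuals of the model against all valid
    points of ``trace``. Standard errors come from the scaled inverse of the
    Gauss-Newton normal matrix; they are NaN when that matrix is singular.
    The exponential-phase window is the pair of data indices closest to the
    model's standard phase bounds.
    """
    if model not in SIGMOID_MODELS:
        raise ParameterError(f"model must be one of {SIGMOID_MODELS}, got {model!r}")
    t, y, idx = _valid_points(trace)
    if len(t) < 5:
        raise DataError(f"parametric fitting needs >= 5 valid points, got {len(t)}")
    if np.ptp(y) == 0:
        raise NonIdentifiableError("flat trace: growth parameters are not identifiable")

    a0, mu0, lam0 = _initial_guess(t, y)
    span = float(t[-1] - t[0])
    lo = np.array([1e-12, 1e-12, t[0] - span])
    hi = np.array([max(2.0 * np.max(y), 1e-6), np.inf, t[-1]])
    x0 = np.clip([a0, mu0, lam0], lo + 1e-15, np.minimum(hi, 1e15))

    def residuals(x):
        p = ModelParams(model=model, a=x[0], mu_max=x[1], lam=x[2], n0=trace.n0)
        return model_y(p, t) - y

    try:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            max_nfev=5000, xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        converged = bool(res.success)
    except Exception:
        res, converged = None, False

    if res is None:
        return FitResult(method=model, mu_max=math.nan, converged=False)

    a, mu, lam = (float(v) for v in res.x)
    params = ModelParams(model=model, a=a, mu_max=mu, lam=lam, n0=trace.n0)

    dof = len(t) - 3
    se = {"a": math.nan, "mu_max": math.nan, "lam": math.nan}
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * res.cost / dof)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = dict(zip(("a", "mu_max", "lam"), np.sqrt(diag).tolist()))
        except np.linalg.LinAlgError:
            pass

    ss_res = float(2.0 * res.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf

    t_start, t_end = exp_phase_bounds(params, "standard")
    i_start = int(idx[np.argmin(np.abs(t - t_start))])
    i_end = int(idx[np.argmin(np.abs(t - t_end))])
    window = (i_start, i_end) if i_start < i_end else None

    return FitResult(
        method=model, mu_max=mu, params=params, se=se,
        r_squared=r2, window=window, converged=converged,
    )


def _valid_runs(mask: np.ndarray):
    """Inclusive (start, end) index pairs of maximal runs of True in mask."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def fit_easy_linear(trace: LogTrace, window: int = DEFAULT_WINDOW) -> FitResult:
    """Sliding-window maximum-slope estimation of the growth rate.

    Fits an ordinary least-squares line to every contiguous subsegment of
    exactly ``window`` valid points and keeps the one with the largest
    slope; ties go to the earliest subsegment. The winning subsegment's
    first and last data indices delimit the exponential phase. Too small a
    window tends to overestimate the rate on noisy data.
    """
    if window < 2:
        raise ParameterError(f"Easy Linear window must be >= 2 points, got {window}")
    best = None
    for run_start, run_end in _valid_runs(trace.valid_mask):
        for i in range(run_start, run_end - window + 2):
            j = i + window - 1
            seg_t = trace.times[i : j + 1]
            seg_y = trace.y[i : j + 1]
            slope, intercept, r2, se = _ols(seg_t, seg_y)
            if best is None or slope > best[0]:
                best = (slope, intercept, r2, se, i, j)
    if best is None:
        raise DataError(f"no contiguous run of {window} valid points in the trace")
    slope, intercept, r2, se, i, j = best
    params = None
    if slope > 0:
        params = ModelParams(model="exponential", a=None, mu_max=slope, lam=None, n0=trace.n0)
    return FitResult(
        method="easy_linear", mu_max=slope, params=params,
        se={"mu_max": se}, r_squared=r2, window=(i, j), intercept=intercept,
    )


def fit_manual(trace: LogTrace, t_start: float, t_end: float) -> FitResult:
    """Straight-line fit over a manually selected time window.

    The user picks the log-linear segment by eye; the slope of the
    least-squares line through the valid points with ``t_start <= t <=
    t_end`` is mu_max, and the first/last selected data points delimit the
    exponential phase.
    """
    if not t_start < t_end:
        raise ParameterError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    sel = trace.valid_mask & (trace.times >= t_start) & (trace.times <= t_end)
    idx = np.nonzero(sel)[0]
    if len(idx) < 2:
        raise SelectionError(
            f"selection [{t_start}, {t_end}] contains {len(idx)} valid points; need >= 2"
        )
    slope, intercept, r2, se = _ols(trace.times[idx], trace.y[idx])
    params = None
    if slope > 0:
        params = ModelParams(model="exponential", a=None, mu_max=slope, lam=None, n0=trace.n0)
    return FitResult(
        method="manual", mu_max=slope, params=params,
        se={"mu_max": se}, r_squared=r2,
        window=(int(idx[0]), int(idx[-1])), intercept=intercept,
    )
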