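"""Per-sample growth statistics and replicate aggregation.

From a fit and the underlying blanked trace this module derives the summary
statistics reported per sample:

* doubling time ``ln 2 / mu_max``,
* maximum specific growth rate ``mu_max``,
* lag time (parametric fits only — window methods carry no lag information),
* start/end of the exponential growth phase,
* total doublings ``log2(N_max / N_min)`` from the lowest to the highest
  measured population size,
* doublings within the exponential phase ``mu_max * (t_end - t_start) / ln 2``,
* yield: the maximum measured population size (the fitted plateau
  ``N0 * e^A`` is additionally available on parametric fits).

Any statistic that cannot be determined is NaN, never a fabricated number.
Replicates (samples sharing a name) are grouped in order of first appearance
with NaN-aware mean and sample standard deviation per statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .fitting import FitResult
from .growth_models import SIGMOID_MODELS, exp_phase_bounds, lag_time
from .preprocess import LogTrace

__all__ = ["GrowthParameters", "SummaryGroup", "derive_parameters", "group_replicates", "STAT_FIELDS"]

LN2 = math.log(2.0)

#: the numeric statistics aggregated over replicates
STAT_FIELDS = (
    "doubling_time",
    "mu_max",
    "lag",
    "t_exp_start",
    "t_exp_end",
    "doublings_total",
    "doublings_exp",
    "yield_max",
)


@dataclass
class GrowthParameters:
    """Derived statistics for one sample; NaN marks an undetermined value."""

    doubling_time: float = math.nan
    mu_max: float = math.nan
    lag: float = math.nan
    t_exp_start: float = math.nan
    t_exp_end: float = math.nan
    doublings_total: float = math.nan
    doublings_exp: float = math.nan
    yield_max: float = math.nan
    yield_fitted: float = math.nan  # N0*e^A, parametric fits only
    sample: str = ""
    group: str = ""
    excluded: bool = False
    method: str = ""


@dataclass
class SummaryGroup:
    """Replicate group: per-statistic NaN-aware mean and sample sd."""

    group_name: str
    member_results: list
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_excluded: int = 0


def derive_parameters(
    fit: FitResult | None,
    trace,
    log: LogTrace | None = None,
    lag_definition: str = "standard",
) -> GrowthParameters:
    """Derive the summary statistics from a fit and its blanked trace.

    Data-derived quantities (total doublings, yield) are computed even when
    the fit is absent or unconverged; fit-derived quantities are then NaN.
    For parametric fits the lag and phase bounds come from the model
    landmarks under ``lag_definition``; for window methods they are the
    times of the window endpoints and the lag stays undetermined.
    """
    out = GrowthParameters()
    trace = np.asarray(trace, dtype=float)

    positive = np.isfinite(trace) & (trace > 0)
    if np.any(positive):
        n_max = float(np.max(trace[positive]))
        n_min = float(np.min(trace[positive]))
        out.yield_max = n_max
        out.doublings_total = math.log2(n_max / n_min)

    if fit is None or not fit.converged or not math.isfinite(fit.mu_max) or fit.mu_max <= 0:
        return out

    out.method = fit.method
    out.mu_max = fit.mu_max
    out.doubling_time = LN2 / fit.mu_max

    if fit.method in SIGMOID_MODELS and fit.params is not None:
        out.lag = lag_time(fit.params, lag_definition)
        out.t_exp_start, out.t_exp_end = exp_phase_bounds(fit.params, lag_definition)
        out.yield_fitted = fit.params.n_inf
    elif fit.window is not None and log is not None:
        i, j = fit.window
        out.t_exp_start = float(log.times[i])
        out.t_exp_end = float(log.times[j])

    if math.isfinite(out.t_exp_start) and math.isfinite(out.t_exp_end):
        out.doublings_exp = fit.mu_max * (out.t_exp_end - out.t_exp_start) / LN2
    return out


def _nan_aware(values: list[float]):
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) == 0:
        return math.nan, math.nan
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else math.nan
    return mean, sd


def group_replicates(dataset, results) -> list[SummaryGroup]:
    """Group per-sample results by sample name, in order of first appearance.

    Mean and sample standard deviation (ddof=1) per statistic are computed
    over the determined values of non-excluded members only; a group whose
    members are all excluded reports NaN statistics and its exclusion count.
    """
    order: list[str] = []
    members: dict[str, list[GrowthParameters]] = {}
    for sample, result in zip(dataset.samples, results):
        name = sample.name
        if name not in members:
            members[name] = []
            order.append(name)
        result.excluded = result.excluded or sample.excluded
        members[name].append(result)

    groups = []
    for name in order:
        res = members[name]
        included = [r for r in res if not r.excluded]
        mean, sd = {}, {}
        for stat in STAT_FIELDS:
            mean[stat], sd[stat] = _nan_aware([getattr(r, stat) for r in included])
        groups.append(
            SummaryGroup(
                group_name=name,
                member_results=res,
                mean=mean,
                sd=sd,
                n_excluded=sum(r.excluded for r in res),
            )
        )
    return groups
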