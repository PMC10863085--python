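"""End-to-end plate analysis: dataset -> per-sample growth parameters.

Ties the modules together in the order a plate analysis runs: blank
subtraction with the mean blank trace, optional rolling-average smoothing,
log transformation, fitting with the chosen method, and derivation of the
summary statistics. Blank samples themselves are carried through with all
statistics undetermined so the summary keeps one row per file row.
"""

from __future__ import annotations

import logging

from .errors import GrowthFitError
from .fitting import DEFAULT_WINDOW, fit_easy_linear, fit_parametric
from .growth_params import GrowthParameters, derive_parameters
from .plate_io import GrowthDataset
from .preprocess import blank_correct, log_transform, rolling_smooth

__all__ = ["analyze_dataset"]

logger = logging.getLogger(__name__)


def analyze_dataset(
    dataset: GrowthDataset,
    method: str = "logistic",
    window: int = DEFAULT_WINDOW,
    smooth: int = 1,
    lag_definition: str = "standard",
) -> list[GrowthParameters]:
    """Fit every non-blank sample of a dataset and derive its statistics.

    ``method`` is ``"logistic"``, ``"gompertz"`` or ``"easylinear"``;
    ``window`` is the Easy Linear subsegment size; ``smooth`` the rolling
    window (1 disables smoothing). Samples that cannot be processed (all
    blank-level, non-convergent, too few points) get NaN statistics and the
    batch continues — one result per sample, in file order.
    """
    blanks = dataset.blank_values()
    blank_set = set(dataset.blank_names)
    results: list[GrowthParameters] = []
    for sample in dataset.samples:
        gp = GrowthParameters(sample=sample.name, group=sample.name, excluded=sample.excluded)
        if sample.name not in blank_set:
            corrected = blank_correct(sample.values, blanks)
            if smooth > 1:
                corrected = rolling_smooth(corrected, smooth)
            try:
                log = log_transform(corrected, dataset.times)
                if method in ("logistic", "gompertz"):
                    fit = fit_parametric(log, method)
                elif method in ("easylinear", "easy_linear"):
                    fit = fit_easy_linear(log, window)
                else:
                    raise GrowthFitError(f"unknown fitting method {method!r}")
                gp = derive_parameters(fit, corrected, log, lag_definition)
            except GrowthFitError as exc:
                logger.warning("sample %r not fitted: %s", sample.name, exc)
                gp = derive_parameters(None, corrected)
            gp.sample = sample.name
            gp.group = sample.name
            gp.excluded = sample.excluded
        results.append(gp)
    return results
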