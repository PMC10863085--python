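"""Raw-trace preprocessing: blank correction, smoothing, log transformation.

All fitting in this package happens in logarithmic population space
``y = ln(N/N0)``. This module turns a raw plate-reader trace (OD600, CFU, ...)
into that space:

1. subtract the mean blank trace (medium background),
2. optionally smooth with a centered rolling average,
3. divide by the reference population size N0 and take logs.

N0 is taken as the smallest strictly positive value of the blanked trace, so
``y >= 0`` everywhere it is defined and total doublings counted from the
minimum are consistent with this reference. Points that are non-positive after
blanking (noise dipping below the blank) are masked rather than clipped:
fitters use valid points only and no data are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError, TransformError

__all__ = ["LogTrace", "blank_correct", "rolling_smooth", "log_transform"]


@dataclass
class LogTrace:
    """A log-transformed growth trace ready for fitting.

    Attributes
    ----------
    times:
        Timestamps in hours, same length as ``y``.
    y:
        ``ln(N_i / n0)`` where defined; entries with ``valid_mask`` False are
        NaN placeholders for non-positive measurements.
    n0:
        Reference population size (> 0), in the units of the raw trace.
    valid_mask:
        True where ``y`` is finite and usable for fitting.
    """

    times: np.ndarray
    y: np.ndarray
    n0: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.y)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (len(self.times) == len(self.y) == len(self.valid_mask)):
            raise DimensionError(
                f"times ({len(self.times)}), y ({len(self.y)}) and valid_mask "
                f"({len(self.valid_mask)}) must have equal length"
            )
        if not (self.n0 > 0):
            raise ParameterError(f"n0 must be > 0, got {self.n0}")
        if not np.all(np.isfinite(self.y[self.valid_mask])):
            raise ParameterError("y must be finite wherever valid_mask is set")


def blank_correct(trace, blanks) -> np.ndarray:
    """Subtract the pointwise mean of the blank traces from ``trace``.

    An empty blank list returns the trace unchanged. All series must share
    the dataset time vector (equal lengths).
    """
    trace = np.asarray(trace, dtype=float)
    blanks = [np.asarray(b, dtype=float) for b in blanks]
    for b in blanks:
        if len(b) != len(trace):
            raise DimensionError(
                f"blank length {len(b)} does not match trace length {len(trace)}"
            )
    if not blanks:
        return trace.copy()
    return trace - np.mean(blanks, axis=0)


def rolling_smooth(series, window: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the edges.

    Each output point is the mean of the input points inside a centered
    window of ``window`` points, shrunk symmetrically where the window would
    run off either end, so output length equals input length and
    ``window=1`` is the identity. NaNs are ignored within each window.
    """
    if window < 1:
        raise ParameterError(f"smoothing window must be >= 1, got {window}")
    series = np.asarray(series, dtype=float)
    if window == 1:
        return series.copy()
    n = len(series)
    left = window // 2  # even windows take the extra point on the left
    right = window - 1 - left
    out = np.empty(n)
    for i in range(n):
        # truncate symmetrically: shrink both sides by the larger overhang
        over = max(left - i, right - (n - 1 - i), 0)
        lo = i - max(left - over, 0)
        hi = i + max(right - over, 0)
        win = series[lo : hi + 1]
        out[i] = np.nanmean(win) if np.any(np.isfinite(win)) else np.nan
    return out


def log_transform(series, times) -> LogTrace:
    """Map a blanked series to ``y = ln(N/N0)`` with N0 = min positive value.

    Non-positive points (possible after blank subtraction of noisy data) are
    masked out rather than clipped. Raises :class:`TransformError` when the
    trace has no strictly positive point at all.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) != len(times):
        raise DimensionError(
            f"series length {len(series)} does not match times length {len(times)}"
        )
    positive = np.isfinite(series) & (series > 0)
    if not np.any(positive):
        raise TransformError("trace entirely at or below blank: no positive value to reference")
    n0 = float(np.min(series[positive]))
    y = np.full(len(series), np.nan)
    y[positive] = np.log(series[positive] / n0)
    return LogTrace(times=times, y=y, n0=n0, valid_mask=positive)
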