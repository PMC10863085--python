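"""Reading and writing plate-reader growth tables and per-sample summaries.

The accepted table layout is one curve per row, wide format:

* row 1: the literal label ``time`` followed by T timestamps (hours),
* rows 2..N: a sample name followed by T measurements in population units
  (OD600 by default).

CSV (comma), TSV (tab) and XLSX (first sheet) dialects are supported, all
UTF-8. Sample order is preserved because defaults depend on it: the first
three samples in a file are taken as blanks unless the caller overrides them.
Duplicate sample names are kept — they are replicates and are grouped later.

When a file holds exactly 6, 12, 24, 96 or 384 samples, each sample ordinal
is mapped to a microtiter well label (row letter + column number, row-major);
any other count falls back to plain ordinals.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError, ParseError, TableValidationError

__all__ = [
    "GrowthDataset",
    "Sample",
    "read_growth_table",
    "write_growth_table",
    "well_label",
    "write_summary",
    "SUMMARY_COLUMNS",
]

#: plate geometry (rows, columns) for the standard microtiter formats
PLATE_GEOMETRIES = {6: (2, 3), 12: (3, 4), 24: (4, 6), 96: (8, 12), 384: (16, 24)}

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"

DEFAULT_N_BLANKS = 3


@dataclass
class Sample:
    """One growth curve: a name, its measurements and an exclusion flag."""

    name: str
    values: np.ndarray
    excluded: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GrowthDataset:
    """A shared time vector plus named raw measurement series for all wells.

    Invariants: all series have the same length as ``times``; ``times`` is
    strictly increasing; every blank name refers to a present sample; sample
    order is the file order (defaults depend on it).
    """

    times: np.ndarray
    samples: list[Sample]
    blank_names: list[str] = field(default_factory=list)
    population_unit: str = "OD600"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(~np.isfinite(self.times)):
            raise TableValidationError("timestamps must be finite numbers")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TableValidationError("timestamps must be strictly increasing")
        t = len(self.times)
        for s in self.samples:
            if len(s.values) != t:
                raise DimensionError(
                    f"sample {s.name!r} has {len(s.values)} values but there are {t} timestamps"
                )
        names = {s.name for s in self.samples}
        for b in self.blank_names:
            if b not in names:
                raise TableValidationError(f"blank name {b!r} is not a sample in the dataset")

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def blank_values(self) -> list[np.ndarray]:
        """Measurement series of all samples whose name is a blank name."""
        return [s.values for s in self.samples if s.name in set(self.blank_names)]


def _parse_cell(text: str, row: int, col: int) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric measurement cell {text!r} at row {row}, column {col}"
        ) from None


def _rows_from_source(source, format: str | None) -> list[list]:
    """Yield raw table rows (lists of cell values) from a path or text."""
    if isinstance(source, (str, os.PathLike)) and format is None:
        suffix = Path(source).suffix.lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "xlsx": "xlsx"}.get(suffix)
    if format is None:
        raise ParameterError("format must be given (csv, tsv or xlsx) when it cannot be inferred")
    if format == "xlsx":
        frame = pd.read_excel(source, header=None, dtype=object)
        return [
            [c for c in row if not (isinstance(c, float) and math.isnan(c))]
            for row in frame.values.tolist()
        ]
    if format not in ("csv", "tsv"):
        raise ParameterError(f"unknown table format {format!r}")
    delim = "," if format == "csv" else "\t"
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source, newline="", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh, delimiter=delim)]
    # literal text content
    return [row for row in csv.reader(io.StringIO(str(source)), delimiter=delim)]


def read_growth_table(source, format: str | None = None) -> GrowthDataset:
    """Read a wide-format growth table into a :class:`GrowthDataset`.

    ``source`` may be a file path (format inferred from the extension) or the
    table text itself (``format`` then required). The first data row holds
    the time vector; every following row is a sample name plus one value per
    timestamp. Blanks default to the first three sample names.
    """
    rows = [r for r in _rows_from_source(source, format) if len(r) > 0]
    if not rows:
        raise ParseError("empty table")
    header, *body = rows
    times = [_parse_cell(c, 1, j + 2) for j, c in enumerate(header[1:])]
    t = len(times)
    samples: list[Sample] = []
    for i, row in enumerate(body, start=2):
        name = str(row[0])
        if len(row) - 1 != t:
            raise DimensionError(
                f"row {i} ({name!r}) has {len(row) - 1} values but there are {t} timestamps"
            )
        values = [_parse_cell(c, i, j + 2) for j, c in enumerate(row[1:])]
        samples.append(Sample(name=name, values=np.asarray(values)))
    blank_names = [s.name for s in samples[:DEFAULT_N_BLANKS]]
    return GrowthDataset(times=np.asarray(times), samples=samples, blank_names=blank_names)


def write_growth_table(dataset: GrowthDataset, destination, format: str | None = None) -> None:
    """Write a dataset back to the wide one-curve-per-row table layout."""
    if format is None:
        format = Path(destination).suffix.lower().lstrip(".") or "csv"
    rows = [["time", *(repr(float(v)) for v in dataset.times)]]
    rows += [[s.name, *(repr(float(v)) for v in s.values)] for s in dataset.samples]
    if format == "xlsx":
        numeric = [[r[0], *map(float, r[1:])] for r in rows]
        pd.DataFrame(numeric).to_excel(destination, header=False, index=False)
        return
    delim = {"csv": ",", "tsv": "\t"}.get(format)
    if delim is None:
        raise ParameterError(f"unknown table format {format!r}")
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh, delimiter=delim).writerows(rows)


def well_label(index: int, n_samples: int) -> str:
    """Microtiter well label for the 1-based sample ordinal ``index``.

    For the standard plate sizes (6, 12, 24, 96, 384 samples) ordinals map
    row-major onto the plate: sample 1 -> A1, sample 14 of 96 -> B2. Any
    other sample count returns the ordinal as text.
    """
    if not 1 <= index <= n_samples:
        raise ParameterError(f"sample index {index} out of range [1, {n_samples}]")
    geometry = PLATE_GEOMETRIES.get(n_samples)
    if geometry is None:
        return str(index)
    _, n_cols = geometry
    row, col = divmod(index - 1, n_cols)
    return f"{_ROW_LETTERS[row]}{col + 1}"


#: column order of the per-sample summary CSV
SUMMARY_COLUMNS = [
    "sample",
    "position",
    "group",
    "excluded",
    "method",
    "doubling_time_h",
    "mu_max_per_h",
    "lag_h",
    "t_exp_start_h",
    "t_exp_end_h",
    "doublings_total",
    "doublings_exp",
    "yield_max",
]


def write_summary(results, destination) -> pd.DataFrame:
    """Write per-sample growth parameters as a summary CSV.

    ``results`` is a sequence of :class:`~growthfit.growth_params.GrowthParameters`.
    One row per sample; undetermined values are written as the literal
    ``nan``. Returns the frame that was written (handy for round-trip tests).
    """
    n = len(results)
    records = []
    for i, r in enumerate(results, start=1):
        records.append(
            {
                "sample": r.sample,
                "position": well_label(i, n),
                "group": r.group if r.group else r.sample,
                "excluded": r.excluded,
                "method": r.method,
                "doubling_time_h": r.doubling_time,
                "mu_max_per_h": r.mu_max,
                "lag_h": r.lag,
                "t_exp_start_h": r.t_exp_start,
                "t_exp_end_h": r.t_exp_end,
                "doublings_total": r.doublings_total,
                "doublings_exp": r.doublings_exp,
                "yield_max": r.yield_max,
            }
        )
    frame = pd.DataFrame.from_records(records, columns=SUMMARY_COLUMNS)
    # stringify floats with shortest round-trip repr so the CSV preserves
    # every numeric bit-exactly; undetermined values become the literal "nan"
    printable = frame.copy()
    for col in printable.columns:
        if printable[col].dtype.kind == "f":
            printable[col] = [
                "nan" if not math.isfinite(v) else repr(float(v)) for v in printable[col]
            ]
    printable.to_csv(destination, index=False, na_rep="nan")
    return frame
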