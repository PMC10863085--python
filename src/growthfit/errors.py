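"""Exception hierarchy for growthfit.

All package-specific failures derive from :class:`GrowthFitError` so callers
can catch one base class when batch-processing whole plates.
"""


class GrowthFitError(Exception):
    """Base class for all growthfit errors."""


class ParseError(GrowthFitError):
    """A cell in an input table could not be interpreted as a number."""


class DimensionError(GrowthFitError):
    """Series lengths disagree (ragged rows, mismatched traces)."""


class TableValidationError(GrowthFitError):
    """A structural invariant of an input table is violated (e.g. non-increasing times)."""


class ParameterError(GrowthFitError):
    """An algorithm parameter is out of its admissible range."""


class TransformError(GrowthFitError):
    """Log transformation impossible (trace entirely at or below blank)."""


class DataError(GrowthFitError):
    """Not enough usable data points for the requested operation."""


class NonIdentifiableError(GrowthFitError):
    """The data carry no information about the model parameters (e.g. flat trace)."""


class SelectionError(GrowthFitError):
    """A manually selected time window contains too few points."""


class UnsupportedModelError(GrowthFitError):
    """The requested quantity is undefined for this growth model."""


class NumericalError(GrowthFitError):
    """A numerical routine (root bracketing, bisection) failed."""


class ValidationRunError(GrowthFitError):
    """The synthetic validation study failed (e.g. excessive non-convergence)."""
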