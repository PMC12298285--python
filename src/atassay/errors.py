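"""Exception hierarchy for the assay pipeline.

All package errors derive from :class:`AssayError` so callers can catch one
base class; subclasses also derive from the closest builtin (ValueError /
RuntimeError) to keep duck-typed call sites working.
"""


class AssayError(Exception):
    """Base class for all atassay errors."""


class InvalidConfigError(AssayError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(AssayError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class SaturationError(AssayError, RuntimeError):
    """Photon counts were acquired above the PMT saturation voltage."""


class WindowError(AssayError, ValueError):
    """A rate window is empty, inverted, or outside the trace span."""


class StateError(AssayError, RuntimeError):
    """An operation was applied in the wrong pipeline state (e.g. double
    dark subtraction)."""


class InsufficientDataError(AssayError, ValueError):
    """Too few observations to compute the requested statistic."""


class DataQualityError(AssayError, RuntimeError):
    """Corrected counts are unusable (e.g. nonpositive at a rate endpoint)."""


class RankDeficiencyError(AssayError, ValueError):
    """Regression design has no variation in the predictor."""


class IllConditionedCalibrationError(AssayError, ValueError):
    """Calibration slope too close to zero for inverse prediction."""


class UndefinedCVError(AssayError, ValueError):
    """Coefficient of variation undefined (zero mean)."""


class ParseError(AssayError, ValueError):
    """A trace or record file violates the expected dialect."""
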