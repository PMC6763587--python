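"""Exception hierarchy for the alphacog pipeline.

Every error raised by the package derives from :class:`AlphacogError`, so
callers can fence off pipeline failures without catching unrelated
exceptions. Per-unit (subject x cap x phase) failures inside the study
pipeline are caught, recorded in the report, and do not abort the run.
"""


class AlphacogError(Exception):
    """Base class for all alphacog errors."""


class FormatError(AlphacogError):
    """A file could not be parsed as the expected format (e.g. truncated EDF)."""


class UnsupportedFormatError(AlphacogError):
    """A file parsed but uses a feature the package does not support."""


class ValidationError(AlphacogError):
    """An in-memory object violates one of its invariants."""


class ConfigurationError(AlphacogError):
    """A configuration value is outside its admissible range."""


class MissingPhaseError(AlphacogError):
    """A requested paradigm phase has no annotation in the recording."""


class InsufficientDataError(AlphacogError):
    """A segment is too short for the requested operation (< 30 s)."""


class FilterError(AlphacogError):
    """Filtering produced non-finite output or an unstable realization."""


class DegenerateReferenceError(AlphacogError):
    """Fewer than two good channels: the average reference is undefined."""


class InterpolationRefusedError(AlphacogError):
    """Too few good channels to build a spherical-spline interpolant."""


class ContractViolationError(AlphacogError):
    """An operation was called outside its stated precondition."""


class InsufficientSubjectsError(AlphacogError):
    """Fewer than three complete subjects remain for inference."""


class DegenerateDataError(AlphacogError):
    """Zero error variance (or similar degeneracy) in the ANOVA strata."""
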