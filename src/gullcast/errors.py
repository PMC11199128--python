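"""Exception hierarchy shared across gullcast modules."""


class GullcastError(Exception):
    """Base class for all gullcast errors."""


class FormatError(GullcastError):
    """Malformed input: missing variable, wrong vector length, bad CSV row."""


class UnsupportedGridError(FormatError):
    """Grid is not a regular lat-lon raster."""


class DomainError(GullcastError):
    """A queried point or region lies outside the grid hull."""


class TimeRangeError(GullcastError):
    """A queried instant lies outside the field's time coverage."""


class EmptyDayError(GullcastError):
    """A calendar day contains no snapshots."""


class CoverageError(GullcastError):
    """Wind (or other field) coverage is too short for the requested
    trajectory or sampling window."""


class TrainingError(GullcastError):
    """Self-organizing-map training preconditions violated."""


class DegenerateCovariateError(GullcastError):
    """A covariate has zero variance and cannot be scaled."""
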