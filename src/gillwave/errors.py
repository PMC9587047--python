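"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`GillwaveError`
so that the pipeline can distinguish "this segment is unusable" (mark
invalid, continue) from genuine programming errors.
"""


class GillwaveError(Exception):
    """Base class for all package errors."""


class FormatError(GillwaveError):
    """A file is missing required metadata or has an unparseable layout."""


class ShapeError(GillwaveError):
    """Array dimensions are inconsistent (e.g. ragged channels)."""


class SpecError(GillwaveError):
    """A parameter specification is invalid for the data it is applied to."""


class DomainError(GillwaveError):
    """An input value is outside the mathematical domain of an operation."""


class EmptyRoiError(GillwaveError):
    """A region of interest encloses no pixel centers."""


class DegenerateSegmentError(GillwaveError):
    """A segment is (near-)constant and cannot be standardized."""


class OrderError(GillwaveError):
    """Requested autoregressive order is too high for the segment length."""


class NoPeakError(GillwaveError):
    """The spectrum is flat in the search band; no peak frequency exists."""


class UndefinedTachogramError(GillwaveError):
    """Fewer than two events: intervals, and hence the tachogram, undefined."""


class SelectionError(GillwaveError):
    """An electrode-selection window contains no tracked frames."""


class AlignmentError(GillwaveError):
    """Selection windows do not tile the recording they are applied to."""


class SectionError(GillwaveError):
    """A piecewise dose section is empty or has fewer than two dose groups."""


class ConvergenceError(GillwaveError):
    """No candidate mixed model converged; selection impossible."""


class ConfigError(GillwaveError):
    """Run configuration failed schema validation."""
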