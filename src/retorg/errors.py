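"""Exception hierarchy for the retorg pipeline.

Every stage raises a dedicated subclass of :class:`RetorgError` so callers can
distinguish configuration mistakes from data-driven failures (a band that is
genuinely absent from a profile, a recording too short to block-average, ...).
"""


class RetorgError(Exception):
    """Base class for all retorg errors."""


class InvalidParameterError(RetorgError, ValueError):
    """A numeric parameter is outside its valid domain."""


class RenderError(RetorgError):
    """The phantom cannot be rendered (e.g. layers exceed the axial window)."""


class FormatError(RetorgError):
    """An on-disk volume/recording does not match its metadata sidecar."""


class DetectionError(RetorgError):
    """Too few A-lines yielded a confident ELM peak."""


class ProtocolError(RetorgError):
    """Input data do not satisfy the acquisition protocol a step requires."""


class SegmentationError(RetorgError):
    """A mandatory band or boundary could not be located on a profile."""


class NormalizationError(RetorgError):
    """ONL normalization is impossible (non-positive reference intensity)."""


class KineticsError(RetorgError):
    """Band tracking failed in too many M-scan columns."""


class AggregationError(RetorgError):
    """M-scans with incompatible grids cannot be averaged."""


class DegenerateVarianceError(RetorgError):
    """A statistical test is undefined because a variance term is zero."""


class InferenceError(RetorgError):
    """Not enough subjects/observations for the requested test."""


class UndefinedFractionError(RetorgError, ZeroDivisionError):
    """A ratio with a zero denominator was requested."""
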