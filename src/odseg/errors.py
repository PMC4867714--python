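"""Exception hierarchy for odseg.

All failures raised by the library derive from :class:`OdsegError`, so callers
can distinguish "this input could never work" (:class:`InvalidInputError`,
:class:`ParameterError`) from "the method ran and found nothing"
(:class:`DetectionFailureError`, :class:`SegmentationFailureError`).
"""


class OdsegError(Exception):
    """Base class for all odseg errors."""


class InvalidInputError(OdsegError):
    """Input data violates a structural precondition (shape, channels, range)."""


class ParameterError(OdsegError):
    """A configuration or function parameter is out of its valid range."""


class DetectionFailureError(OdsegError):
    """No optic-disc circle was found at any sensitivity level."""


class SegmentationFailureError(OdsegError):
    """Grow-cut produced no usable foreground component."""


class InvalidSeedError(OdsegError):
    """Seed specification yields empty or overlapping seed regions."""


class EllipseFitError(OdsegError):
    """Boundary points are too few or too degenerate for an ellipse fit."""
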