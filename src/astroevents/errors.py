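"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 2, everything else -> 3.
"""


class AstroEventsError(Exception):
    """Base class for all package errors."""


class ValidationError(AstroEventsError):
    """Invalid configuration or arguments."""


class FormatError(AstroEventsError):
    """Unreadable or ambiguous input file."""


class BoundsError(ValidationError):
    """Window coordinates outside the stored array."""


class DegenerateTraceError(AstroEventsError):
    """Peak masking would remove every frame of a trace."""


class InterpolationError(AstroEventsError):
    """Background interpolation cannot be performed."""


class NormalizationError(AstroEventsError):
    """A normalization step produced an undefined result."""


class UndefinedCorrelationError(AstroEventsError):
    """Pearson correlation undefined (zero-variance trace)."""


class DegenerateLabelError(AstroEventsError):
    """Coincidence labelling produced a single class."""


class PlacementError(AstroEventsError):
    """Could not place synthetic events with the requested separation."""
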