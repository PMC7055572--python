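"""Exception hierarchy shared across the pipeline stages."""


class GifaError(Exception):
    """Base class for all gifa errors."""


class InvalidSpecError(GifaError, ValueError):
    """A synthetic-data specification is infeasible or out of range."""


class InvalidParameterError(GifaError, ValueError):
    """An operation parameter violates its contract."""


class InvalidInputError(GifaError, ValueError):
    """Input arrays/tables are malformed or geometrically inconsistent."""


class EmptySegmentationError(GifaError, ValueError):
    """A segmentation step produced (or received) an empty mask."""


class InconsistentMaskError(GifaError, ValueError):
    """A mask violates a required subset/geometry relationship."""


class InsufficientMinorityError(GifaError, ValueError):
    """The minority class is too small for SMOTE interpolation."""


class UndefinedMetricError(GifaError, ValueError):
    """A statistic is undefined for the given input (e.g. one class only)."""


class ParseError(GifaError, ValueError):
    """A case-table file violates the expected schema."""
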