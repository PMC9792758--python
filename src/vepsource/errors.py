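"""Exception hierarchy shared across the pipeline stages."""


class VepSourceError(Exception):
    """Base class for all package-specific errors."""


class MontageError(VepSourceError):
    """Montage structure violates an invariant (count, anchors, geometry)."""


class ParseError(VepSourceError):
    """A text artifact could not be parsed."""


class GeometryError(VepSourceError):
    """A source position is outside the head model."""


class EpochError(VepSourceError):
    """Epoch extraction failed (e.g. truncated windows)."""


class DataQualityError(VepSourceError):
    """Data quality too poor to continue (e.g. every epoch rejected)."""


class SingularityError(VepSourceError):
    """Field or potential evaluated at the source location."""


class DegenerateInputError(VepSourceError):
    """Input carries no usable signal (all-zero data, zero moment)."""


class ConvergenceError(VepSourceError):
    """An iterative solver failed to converge."""


class PeakNotFoundError(VepSourceError):
    """No qualifying peak inside the search window."""


class CorrelationUndefinedError(VepSourceError):
    """Correlation requested on a zero-variance input."""
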