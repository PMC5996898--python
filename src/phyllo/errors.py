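"""Exception hierarchy shared across the package."""


class PhylloError(Exception):
    """Base class for all errors raised by phyllo."""


class ParseError(PhylloError, ValueError):
    """A contour or manifest file could not be parsed."""


class ValidationError(PhylloError, ValueError):
    """An input violates a structural invariant (too few points, NaNs, ...)."""


class DegenerateContourError(PhylloError, ValueError):
    """A contour collapses to a point or a zero-length polyline."""


class DegenerateShapeError(PhylloError, ValueError):
    """A polygon has zero area/perimeter or a degenerate convex hull."""


class ConfigurationError(PhylloError, ValueError):
    """A parameter is outside its allowed range."""


class ClassificationError(PhylloError, ValueError):
    """The classifier cannot be trained (singular covariance, no usable classes)."""


class GenerationError(PhylloError, RuntimeError):
    """The synthetic-leaf generator failed to produce a valid outline."""
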