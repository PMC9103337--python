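"""Exception hierarchy.

Every error raised by the library derives from :class:`OviThermError`, so
callers batch-processing many eggs can catch one base class, flag the item
and move on.
"""


class OviThermError(Exception):
    """Base class for all ovitherm errors."""


class ConfigurationError(OviThermError):
    """Required metadata or configuration is missing or inconsistent."""


class FormatError(OviThermError):
    """An input file does not satisfy the expected layout (e.g. mixed frame shapes)."""


class IntegrityError(OviThermError):
    """A table violates its key constraints (duplicates, empty record sets)."""


class DataError(OviThermError):
    """Input pixel data is unusable (NaN frames, empty stacks)."""


class InsufficientDataError(OviThermError):
    """Too few frames to perform the requested transform."""


class ParameterError(OviThermError):
    """A parameter is outside its valid range."""


class RangeError(OviThermError):
    """A requested time/index lies beyond the acquired sequence."""


class DetectionError(OviThermError):
    """Calibration-grid blob detection failed."""


class GeometryError(OviThermError):
    """Degenerate geometry (coincident centers, empty bounding box, grid out of bounds)."""


class SegmentationError(OviThermError):
    """No usable foreground component found."""


class InsufficientPointsError(OviThermError):
    """Fewer boundary points than the five an ellipse fit requires."""


class FitError(OviThermError):
    """The conic fit did not produce a valid ellipse."""


class UngradableError(OviThermError):
    """Freshness grading requested without a chamber-height measurement."""


class NormalizationError(OviThermError):
    """First-day reference value missing or non-positive."""


class RegressionError(OviThermError):
    """Not enough points for the requested polynomial order."""


class PhantomError(OviThermError):
    """Synthetic phantom parameters are geometrically inconsistent."""
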