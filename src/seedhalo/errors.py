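"""Exception hierarchy for seedhalo.

All errors raised by the library derive from :class:`SeedHaloError` so
callers (and the CLI) can catch everything from one base class.
"""


class SeedHaloError(Exception):
    """Base class for all seedhalo errors."""


class ImageFormatError(SeedHaloError):
    """Input raster is not an 8-bit RGB image of the expected shape."""


class CalibrationError(SeedHaloError):
    """Invalid spatial calibration (coincident points, non-positive scale)."""


class BoundsError(SeedHaloError):
    """A crop window or index falls outside the image."""


class ParameterError(SeedHaloError):
    """Invalid segmentation parameters or unknown target."""


class DegenerateHistogramError(SeedHaloError):
    """Histogram has fewer than two populated bins; no threshold exists."""


class EmptyRegionError(SeedHaloError):
    """A morphometric descriptor was requested for an empty region."""


class UndefinedMetricError(SeedHaloError):
    """A descriptor is undefined for this input (e.g. zero perimeter/area)."""


class ConfigError(SeedHaloError):
    """Invalid run configuration."""


class PipelineError(SeedHaloError):
    """The analysis pipeline could not complete (e.g. empty segmentation)."""
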