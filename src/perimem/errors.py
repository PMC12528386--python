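"""Exception hierarchy for the measurement pipeline.

Pipeline stages raise these instead of bare ValueErrors so that batch
drivers can catch per-image failures without masking programming errors.
"""


class PerimemError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(PerimemError, ValueError):
    """A configuration or generator parameter violates its constraint."""


class ImageFormatError(PerimemError):
    """The raster on disk is not a 2D grayscale image we can handle."""


class CalibrationError(PerimemError):
    """No pixel size available: neither in metadata nor given explicitly."""


class RoiBoundsError(PerimemError):
    """An ROI record does not fit inside the image it annotates."""


class NoMembraneError(PerimemError):
    """Segmentation produced no membrane pixels (or none above min area)."""


class NoPathError(PerimemError):
    """Skeletonization left no usable centerline after pruning."""


class AllExcludedError(PerimemError):
    """Pole exclusion removed the entire path."""


class TooShortError(PerimemError):
    """A ribbon or path is shorter than one measurement segment."""


class SamplingBoundsError(PerimemError):
    """Straightening would sample intensities outside the image bounds."""
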