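"""Exception hierarchy.

Every failure raised by the library derives from :class:`AnthroscanError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class AnthroscanError(Exception):
    """Base class for all anthroscan errors."""


class ValidationError(AnthroscanError, ValueError):
    """Invalid argument or inconsistent input data."""


class EmptyCloudError(ValidationError):
    """An operation received a point cloud with no points."""


class FormatError(AnthroscanError):
    """A point-cloud file could not be parsed."""


class LandmarkError(AnthroscanError):
    """A segmentation landmark could not be located."""


class NoArmFoundError(LandmarkError):
    """No arm junction detected on a side of the upper-body contour."""


class ContourError(AnthroscanError):
    """The upper-body outline could not be extracted."""


class EmptySlabError(AnthroscanError):
    """A measurement slab contains no points (bad site or too-thin slab)."""


class DegenerateSlabError(AnthroscanError):
    """A slab has fewer than 3 non-collinear points; no perimeter exists."""
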