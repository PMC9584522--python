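"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`PlumaquantError`
so callers (and the CLI) can catch one base type.
"""


class PlumaquantError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PlumaquantError, ValueError):
    """A generator or operation spec violates its preconditions."""


class FrameTooSmallError(PlumaquantError, ValueError):
    """Image smaller than a single interrogation box."""


class GridMismatchError(PlumaquantError, ValueError):
    """Grid geometry does not match the frame it is applied to."""


class NoValidBoxesError(PlumaquantError, ValueError):
    """Averaging requested over an empty or all-degenerate box subset."""


class InsufficientPointsError(PlumaquantError, ValueError):
    """Too few points for a spacing statistic."""


class DegenerateGeometryError(PlumaquantError, ValueError):
    """Point set is collinear or too small to triangulate."""


class NoInteriorEdgesError(PlumaquantError, ValueError):
    """All triangulation vertices lie on the convex hull."""


class InvalidRoiError(PlumaquantError, ValueError):
    """Region of interest has zero area or lies outside the frame."""


class UnknownLabelError(PlumaquantError, KeyError):
    """Component label absent from a PrimordiumSet."""


class InvalidPolygonError(PlumaquantError, ValueError):
    """Outline is not a simple polygon with >= 3 vertices."""


class FrameMismatchError(PlumaquantError, ValueError):
    """Frames in a stack disagree in geometry."""


class GridTooSmallError(PlumaquantError, ValueError):
    """Anisotropy grid too small for region auto-detection."""


class InvalidTrefError(PlumaquantError, ValueError):
    """Reference frame index outside the series."""


class RegionOutOfBoundsError(PlumaquantError, ValueError):
    """Requested region extends past the velocity field."""


class FieldTooSmallError(PlumaquantError, ValueError):
    """Velocity field too small for finite-difference divergence."""


class FormatError(PlumaquantError, ValueError):
    """File is not a readable grayscale TIFF."""


class UnsupportedChannelsError(PlumaquantError, ValueError):
    """Multi-channel (RGB) image; channels must be pre-split."""


class IoError(PlumaquantError, OSError):
    """Output location is not writable."""
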