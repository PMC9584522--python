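"""Core image container.

An :class:`ImageFrame` couples a 2D grayscale intensity array with the
physical pixel size (and, for movie frames, a timestamp).  Axis 0 (rows)
is by convention the antero-posterior (AP) body axis and axis 1 (cols)
the dorso-ventral (DV) axis; x denotes the column coordinate and y the
row coordinate throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

__all__ = ["ImageFrame"]


@dataclass
class ImageFrame:
    """One grayscale image with physical calibration.

    Parameters
    ----------
    pixels :
        2D array of finite, non-negative intensities (rows x cols).
    pixel_size_um :
        Physical size of one pixel in micrometres, > 0.
    timestamp_min :
        Acquisition time in minutes for movie frames, or ``None``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    timestamp_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidSpecError("pixels must be a 2D array")
        if self.pixel_size_um <= 0:
            raise InvalidSpecError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidSpecError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise InvalidSpecError("pixel intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the frame in micrometres."""
        h, w = self.pixels.shape
        return h * self.pixel_size_um, w * self.pixel_size_um

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        """Copy of this frame with new pixel data, same calibration."""
        return ImageFrame(pixels, self.pixel_size_um, self.timestamp_min)
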