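"""Segmentation-free coarse-grained cell-shape anisotropy by Fourier transform.

The image is tiled into square interrogation boxes (25 x 25 um with 50%
overlap by default).  Each box is mean-subtracted, apodised with a 2D
Hann window, Fourier transformed, and the spectrum modulus binarised by
keeping its 5% brightest pixels; the retained pixels form a filled
ellipse whose second-moment (inertia) matrix is diagonalised.  With
eigenvalues ``l1 >= l2`` the anisotropy amplitude is

    a = (1/2) ln(L_maj / L_min) = (1/4) ln(l1 / l2),

a dimensionless number equal to zero for an isotropic texture.  Because
elongation in real space compresses the spectrum along the same axis,
the real-space elongation orientation is the eigenvector of the *minor*
spectral eigenvalue; it is nematic (defined modulo 180 degrees) and is
reported in [0, pi) counter-clockwise from the AP (row) axis.

No cell segmentation is performed anywhere: the statistic is a property
of the box texture as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    FrameTooSmallError,
    GridMismatchError,
    InvalidSpecError,
    NoValidBoxesError,
)
from .frames import ImageFrame

__all__ = [
    "InterrogationGrid",
    "AnisotropyMap",
    "make_grid",
    "box_anisotropy",
    "anisotropy_map",
    "average_anisotropy",
]

#: Sentinel angle for degenerate boxes.
ANGLE_SENTINEL = np.nan

#: Fraction of spectrum pixels retained by the binarisation.
SPECTRUM_KEEP_FRACTION = 0.05


@dataclass(frozen=True)
class InterrogationGrid:
    """Regular tiling of a frame into square interrogation boxes.

    The tiling is anchored at pixel (0, 0) with stride
    ``box_size_px * (1 - overlap_fraction)`` (rounded, >= 1); boxes that
    would overrun the frame are dropped, never truncated.
    """

    box_size_um: float
    overlap_fraction: float
    box_size_px: int
    stride_px: int
    n_rows_boxes: int
    n_cols_boxes: int
    frame_shape: tuple[int, int]
    pixel_size_um: float

    @property
    def box_origins(self) -> list[tuple[int, int]]:
        """(row, col) pixel offsets of every box, row-major."""
        return [
            (r * self.stride_px, c * self.stride_px)
            for r in range(self.n_rows_boxes)
            for c in range(self.n_cols_boxes)
        ]

    def box_center_um(self, box_row: int, box_col: int) -> tuple[float, float]:
        """(x, y) centre of a box in micrometres."""
        half = (self.box_size_px - 1) / 2.0
        y = (box_row * self.stride_px + half) * self.pixel_size_um
        x = (box_col * self.stride_px + half) * self.pixel_size_um
        return x, y


@dataclass
class AnisotropyMap:
    """Per-box anisotropy amplitude and nematic orientation.

    ``amplitude[r, c]`` is (1/2) ln(L_maj/L_min) for box (r, c);
    ``angle_rad`` the real-space elongation orientation in [0, pi) from
    the AP axis (NaN where degenerate); ``degenerate`` flags boxes with
    no usable signal (those carry amplitude 0).
    """

    amplitude: np.ndarray
    angle_rad: np.ndarray
    degenerate: np.ndarray
    grid: InterrogationGrid

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def make_grid(
    frame: ImageFrame,
    box_size_um: float = 25.0,
    overlap_fraction: float = 0.5,
) -> InterrogationGrid:
    """Build the interrogation-box tiling for a frame.

    Raises ``FrameTooSmallError`` if the frame cannot hold one full box
    and ``InvalidSpecError`` if the box converts to fewer than 8 px.
    """
    if not (0 <= overlap_fraction < 1):
        raise InvalidSpecError("overlap_fraction must be in [0, 1)")
    box_px = int(round(box_size_um / frame.pixel_size_um))
    if box_px < 8:
        raise InvalidSpecError(
            f"box of {box_size_um} um is {box_px} px at this pixel size; need >= 8 px"
        )
    h, w = frame.shape
    if h < box_px or w < box_px:
        raise FrameTooSmallError(
            f"frame {h}x{w} px smaller than one {box_px} px box"
        )
    stride = max(1, int(round(box_px * (1 - overlap_fraction))))
    n_rows = (h - box_px) // stride + 1
    n_cols = (w - box_px) // stride + 1
    return InterrogationGrid(
        box_size_um=box_size_um,
        overlap_fraction=overlap_fraction,
        box_size_px=box_px,
        stride_px=stride,
        n_rows_boxes=n_rows,
        n_cols_boxes=n_cols,
        frame_shape=(h, w),
        pixel_size_um=frame.pixel_size_um,
    )


def _hann2d(n: int) -> np.ndarray:
    w = np.hanning(n)
    return np.outer(w, w)


def box_anisotropy(box_pixels: np.ndarray) -> tuple[float, float, bool]:
    """Anisotropy amplitude and orientation of one interrogation box.

    Returns ``(amplitude, angle_rad, degenerate)``.  Pipeline: subtract
    the box mean, apply a 2D Hann window, take the centred 2D FFT
    modulus, keep pixels at or above its nearest-rank 95th percentile
    (ties retained), form the second-moment matrix of the retained
    pixel coordinates about the zero-frequency origin with uniform
    weights, and diagonalise.  Degenerate boxes (zero signal, or fewer
    than 3 non-collinear retained pixels) return (0, NaN, True).
    """
    box = np.asarray(box_pixels, dtype=float)
    n = box.shape[0]
    if box.ndim != 2 or box.shape[0] != box.shape[1]:
        raise InvalidSpecError("interrogation box must be square")
    if n < 8:
        raise InvalidSpecError("interrogation box side must be >= 8 px")

    signal = box - box.mean()
    if not np.any(signal):
        return 0.0, ANGLE_SENTINEL, True
    windowed = signal * _hann2d(n)
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(windowed)))

    flat = np.sort(spectrum.ravel())
    # nearest-rank 95th percentile
    rank = int(np.ceil((1 - SPECTRUM_KEEP_FRACTION) * flat.size)) - 1
    threshold = flat[rank]
    keep = spectrum >= threshold
    rows, cols = np.nonzero(keep)
    if len(rows) < 3:
        return 0.0, ANGLE_SENTINEL, True

    cy = n // 2  # zero-frequency pixel after fftshift
    dy = rows - cy
    dx = cols - cy
    inertia = np.array(
        [
            [np.mean(dy * dy), np.mean(dy * dx)],
            [np.mean(dy * dx), np.mean(dx * dx)],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(inertia)  # ascending
    l2, l1 = float(eigvals[0]), float(eigvals[1])
    if l2 <= 0:  # retained pixels collinear
        return 0.0, ANGLE_SENTINEL, True
    amplitude = 0.25 * float(np.log(l1 / l2))
    # real-space elongation is along the spectrum's minor axis
    vy, vx = eigvecs[0, 0], eigvecs[1, 0]
    angle = float(np.arctan2(vx, vy)) % np.pi
    return amplitude, angle, False


def anisotropy_map(frame: ImageFrame, grid: InterrogationGrid) -> AnisotropyMap:
    """Apply :func:`box_anisotropy` to every box of the grid."""
    if grid.frame_shape != frame.shape:
        raise GridMismatchError(
            f"grid built for {grid.frame_shape}, frame is {frame.shape}"
        )
    nr, nc = grid.n_rows_boxes, grid.n_cols_boxes
    amp = np.zeros((nr, nc))
    ang = np.full((nr, nc), ANGLE_SENTINEL)
    deg = np.zeros((nr, nc), dtype=bool)
    b = grid.box_size_px
    s = grid.stride_px
    for r in range(nr):
        for c in range(nc):
            block = frame.pixels[r * s : r * s + b, c * s : c * s + b]
            amp[r, c], ang[r, c], deg[r, c] = box_anisotropy(block)
    return AnisotropyMap(amp, ang, deg, grid)


def average_anisotropy(
    amap: AnisotropyMap,
    box_subset: list[tuple[int, int]] | None = None,
) -> tuple[float, float | None]:
    """Mean anisotropy amplitude and mean nematic direction over boxes.

    The amplitude is the arithmetic mean of per-box amplitudes (the
    "mean of all bar lengths"); the direction is the orientation of the
    amplitude-weighted mean nematic tensor sum a_i (cos 2t_i, sin 2t_i).
    When that tensor nearly cancels (norm < 1e-9 of the amplitude sum)
    the direction is undefined and ``None`` is returned for it.
    Degenerate boxes are excluded; an empty or all-degenerate subset
    raises ``NoValidBoxesError``.
    """
    if box_subset is None:
        rr, cc = np.nonzero(~amap.degenerate)
        boxes = list(zip(rr.tolist(), cc.tolist()))
    else:
        boxes = [
            (r, c) for (r, c) in box_subset if not amap.degenerate[r, c]
        ]
    if not boxes:
        raise NoValidBoxesError("no non-degenerate boxes in subset")
    amps = np.array([amap.amplitude[r, c] for r, c in boxes])
    angs = np.array([amap.angle_rad[r, c] for r, c in boxes])
    mean_amp = float(amps.mean())
    qx = float(np.sum(amps * np.cos(2 * angs)))
    qy = float(np.sum(amps * np.sin(2 * angs)))
    total = float(np.sum(amps))
    if total <= 0 or np.hypot(qx, qy) < 1e-9 * total:
        return mean_amp, None
    return mean_amp, float((0.5 * np.arctan2(qy, qx)) % np.pi)
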