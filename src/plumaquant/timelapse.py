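"""Dynamic analysis of skin-explant movies.

The stages mirror a time-lapse quantification workflow: translation
drift registration, automatic detection of the competent segment and of
primordium / inter-primordium regions from the temporal mean anisotropy,
moving-average smoothing with alignment on a reference time point
(t_ref, the first visible primordium condensation), particle image
velocimetry (PIV) for tissue motility, divergence of the velocity field
(negative = convergence / condensation), and antero-posterior tracking
of detected primordia with fusion events.

Axis conventions: image rows are the antero-posterior (AP) axis and
grid columns index dorso-ventral (DV) positions, so one grid column
spans the AP extent of a longitudinal segment; x is the column (DV)
coordinate, y the row (AP) coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    FieldTooSmallError,
    FrameMismatchError,
    GridTooSmallError,
    InvalidSpecError,
    InvalidTrefError,
    RegionOutOfBoundsError,
)
from .frames import ImageFrame
from .pattern import PrimordiumSet, detect_primordia

__all__ = [
    "RegionAssignment",
    "VelocityField",
    "AlignedSeries",
    "PrimordiumTrack",
    "register_drift",
    "detect_regions",
    "smooth_and_align",
    "aggregate_aligned",
    "compute_piv",
    "region_motility",
    "field_divergence",
    "track_primordia",
]


@dataclass
class RegionAssignment:
    """Automatically detected analysis regions on the anisotropy grid.

    The competent segment is the 3 adjacent grid columns with maximal
    averaged anisotropy.  Within it, the inter-primordium (IP) region is
    the 4 boxes of maximal mean amplitude and the primordium (P) region
    the 4 of minimal mean amplitude; each is enlarged to a 3x3 block of
    9 boxes centred on the 4-box centroid, with the central column
    forced to the segment's middle column and rows clamped to the grid.
    """

    segment_cols: tuple[int, int, int]
    ip_boxes_4: list[tuple[int, int]]
    p_boxes_4: list[tuple[int, int]]
    ip_boxes_9: list[tuple[int, int]]
    p_boxes_9: list[tuple[int, int]]


@dataclass
class VelocityField:
    """Per-box 2D tissue velocity in um/h.

    ``u`` is the x (column) component, ``v`` the y (row) component.
    ``valid`` is False where the raw PIV vector was degenerate or
    rejected as an outlier; such vectors carry their median-infilled
    values but keep the flag for provenance.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    box_stride_um: float
    n_outliers_replaced: int = 0

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass
class AlignedSeries:
    """A smoothed per-frame scalar series aligned on t_ref.

    ``aligned_frames[i]`` is ``frame_i - t_ref_frame``; the physical
    time coordinate is ``aligned_frames * frame_interval_min``.
    """

    values: np.ndarray
    frame_interval_min: float
    t_ref_frame: int
    window_frames: int
    smoothed: bool = True

    @property
    def aligned_frames(self) -> np.ndarray:
        return np.arange(len(self.values)) - self.t_ref_frame

    @property
    def time_min(self) -> np.ndarray:
        return self.aligned_frames * self.frame_interval_min


@dataclass
class PrimordiumTrack:
    """AP-position history of one tracked primordium.

    ``positions_px[k]`` is the AP (row) centroid coordinate at frame
    ``start_frame + k``.  ``fusion_events`` lists ``(frame,
    absorbed_track_id)`` for tracks that merged *into* this one; a track
    that ends by merging into another has ``ended_by_fusion`` set.
    """

    track_id: int
    start_frame: int
    positions_px: list[float] = field(default_factory=list)
    fusion_events: list[tuple[int, int]] = field(default_factory=list)
    ended_by_fusion: bool = False

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions_px) - 1


# ---------------------------------------------------------------------------
# drift registration


def _phase_correlate(a: np.ndarray, b: np.ndarray) -> tuple[int, int, float]:
    """Integer shift (dy, dx) of b relative to a, plus peak confidence.

    Maximises the phase correlation; confidence is the ratio of the
    peak to the second-highest peak outside the peak's 3x3 vicinity.
    """
    fa, fb = np.fft.fft2(a), np.fft.fft2(b)
    cross = np.conj(fa) * fb
    denom = np.abs(cross)
    cross = np.where(denom > 1e-12, cross / np.maximum(denom, 1e-12), 0.0)
    surf = np.fft.ifft2(cross).real
    peak = np.unravel_index(np.argmax(surf), surf.shape)
    h, w = surf.shape
    dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
    dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
    masked = surf.copy()
    yy = (peak[0] + np.arange(-1, 2)) % h
    xx = (peak[1] + np.arange(-1, 2)) % w
    masked[np.ix_(yy, xx)] = -np.inf
    second = float(masked.max())
    confidence = float(surf[peak] / second) if second > 0 else np.inf
    return int(dy), int(dx), confidence


def register_drift(
    frames: list[ImageFrame],
    min_confidence: float = 1.5,
) -> tuple[list[ImageFrame], np.ndarray, np.ndarray]:
    """Translation-only drift correction of a movie.

    Consecutive frame pairs are phase-correlated; cumulative integer
    shifts re-align every frame onto frame 0 (edge-replicated borders).
    Returns ``(aligned_frames, shifts, low_confidence)`` where
    ``shifts[k]`` is the cumulative (dy, dx) applied to frame k and
    ``low_confidence[k]`` flags pairs whose correlation peak was less
    than ``min_confidence`` times the runner-up (e.g. featureless or
    decorrelated frames).
    """
    if len(frames) < 2:
        raise InvalidSpecError("need >= 2 frames to register")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise FrameMismatchError("frames differ in geometry")
    shifts = np.zeros((len(frames), 2), dtype=int)
    low_conf = np.zeros(len(frames), dtype=bool)
    aligned = [frames[0]]
    cum = np.zeros(2, dtype=int)
    for k in range(1, len(frames)):
        dy, dx, conf = _phase_correlate(frames[k - 1].pixels, frames[k].pixels)
        low_conf[k] = conf < min_confidence
        cum = cum + np.array([dy, dx])
        shifts[k] = cum
        moved = ndimage.shift(
            frames[k].pixels, -cum.astype(float), order=0, mode="nearest"
        )
        aligned.append(frames[k].with_pixels(moved))
    return aligned, shifts, low_conf


# ---------------------------------------------------------------------------
# region auto-detection


def detect_regions(per_box_mean_amplitude: np.ndarray) -> RegionAssignment:
    """Locate competent segment and P / IP regions from mean anisotropy.

    Ties are broken toward the smallest starting column (segment) and
    row-major box order (4-box extrema).
    """
    amp = np.asarray(per_box_mean_amplitude, dtype=float)
    if amp.ndim != 2:
        raise InvalidSpecError("amplitude grid must be 2D")
    n_rows, n_cols = amp.shape
    if n_cols < 3:
        raise GridTooSmallError("need >= 3 grid columns")
    if not np.all(np.isfinite(amp)):
        raise InvalidSpecError("amplitude grid must be finite")
    if n_rows * 3 < 8:
        raise GridTooSmallError("segment must contain >= 8 boxes")

    window_means = np.array(
        [amp[:, c : c + 3].mean() for c in range(n_cols - 2)]
    )
    c0 = int(np.argmax(window_means))  # argmax returns first max: tie-break
    segment_cols = (c0, c0 + 1, c0 + 2)

    seg = amp[:, c0 : c0 + 3]
    # row-major stable order among ties
    flat_idx = np.arange(seg.size)
    order_max = sorted(flat_idx, key=lambda i: (-seg.ravel()[i], i))
    order_min = sorted(flat_idx, key=lambda i: (seg.ravel()[i], i))

    def unflatten(ix: int) -> tuple[int, int]:
        return ix // 3, c0 + ix % 3

    ip4 = [unflatten(i) for i in order_max[:4]]
    p4 = [unflatten(i) for i in order_min[:4]]

    def block9(boxes4: list[tuple[int, int]]) -> list[tuple[int, int]]:
        center_row = int(round(np.mean([r for r, _ in boxes4])))
        center_row = min(max(center_row, 1), n_rows - 2)
        mid_col = c0 + 1
        return [
            (center_row + dr, mid_col + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        ]

    return RegionAssignment(segment_cols, ip4, p4, block9(ip4), block9(p4))


# ---------------------------------------------------------------------------
# smoothing / alignment


def smooth_and_align(
    series: np.ndarray,
    t_ref_frame: int,
    window_frames: int = 30,
    frame_interval_min: float = 5.0,
) -> AlignedSeries:
    """Centered moving average re-zeroed at t_ref.

    At each frame the window is truncated symmetrically to stay inside
    the series (half-width ``min(window_frames // 2, i, n-1-i)``), so
    the output has the input's length and a linear ramp is preserved
    exactly.  NaNs are first filled by linear interpolation over frame
    index (evenly spaced query points).
    """
    values = np.asarray(series, dtype=float).copy()
    n = len(values)
    if n < 2:
        raise InvalidSpecError("series must have >= 2 frames")
    if not (0 <= t_ref_frame < n):
        raise InvalidTrefError(f"t_ref frame {t_ref_frame} outside [0, {n})")
    nans = np.isnan(values)
    if nans.any():
        if nans.all():
            raise InvalidSpecError("series is all-NaN")
        idx = np.arange(n)
        values[nans] = np.interp(idx[nans], idx[~nans], values[~nans])
    half = window_frames // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return AlignedSeries(out, frame_interval_min, t_ref_frame, window_frames)


def suggest_t_ref(
    p_region_series: np.ndarray,
    baseline_frames: int = 30,
) -> int | None:
    """Heuristic reference time point from the P-region anisotropy series.

    The first visible condensation is normally identified by eye; this
    optional helper instead proposes the first frame where the
    primordium-region mean amplitude falls more than 2 baseline
    standard deviations below its pre-drop (first ``baseline_frames``)
    mean and stays there for 3 consecutive frames (so single-frame
    noise dips do not trigger).  Returns ``None`` when no such drop
    occurs.  Off by default everywhere: callers must opt in.
    """
    s = np.asarray(p_region_series, dtype=float)
    if len(s) <= baseline_frames:
        return None
    base = s[:baseline_frames]
    mean, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0:
        return None
    below = s[baseline_frames:] < mean - 2 * sd
    sustained = below[:-2] & below[1:-1] & below[2:] if len(below) >= 3 else below[:0]
    hits = np.nonzero(sustained)[0]
    return int(baseline_frames + hits[0]) if len(hits) else None


def aggregate_aligned(series_list: list[AlignedSeries]) -> AlignedSeries:
    """Pointwise mean of several movies on their shared aligned support.

    Series are matched on the aligned frame coordinate (frame - t_ref);
    the result covers the intersection of supports and uses t_ref-frame
    = -(smallest shared aligned frame).
    """
    if not series_list:
        raise InvalidSpecError("no series to aggregate")
    lo = max(s.aligned_frames[0] for s in series_list)
    hi = min(s.aligned_frames[-1] for s in series_list)
    if lo > hi:
        raise InvalidSpecError("aligned supports do not overlap")
    grid = np.arange(lo, hi + 1)
    stacked = np.stack(
        [s.values[grid + s.t_ref_frame] for s in series_list]
    )
    return AlignedSeries(
        stacked.mean(axis=0),
        series_list[0].frame_interval_min,
        int(-lo),
        series_list[0].window_frames,
    )


# ---------------------------------------------------------------------------
# particle image velocimetry


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _subpixel_refine(corr: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """3-point Gaussian peak interpolation per axis on a circular map."""
    n0, n1 = corr.shape

    def refine(cm: float, c0: float, cp: float) -> float:
        if c0 <= 0 or cm <= 0 or cp <= 0:
            return 0.0
        denom = np.log(cm) + np.log(cp) - 2 * np.log(c0)
        if denom >= 0:
            return 0.0
        return float(0.5 * (np.log(cm) - np.log(cp)) / denom)

    dy = refine(corr[(py - 1) % n0, px], corr[py, px], corr[(py + 1) % n0, px])
    dx = refine(corr[py, (px - 1) % n1], corr[py, px], corr[py, (px + 1) % n1])
    return dy, dx


def compute_piv(
    frame_a: ImageFrame,
    frame_b: ImageFrame,
    window_px: int = 32,
    overlap_fraction: float = 0.5,
    frame_interval_min: float = 5.0,
    median_filter_radius_px: int = 2,
    outlier_tolerance_px: float = 2.0,
    subpixel: bool = True,
) -> VelocityField:
    """FFT cross-correlation PIV between two consecutive frames.

    Both frames are median-filtered (disk radius 2 px) to suppress
    aberrant vectors, tiled into interrogation windows (32 px, 50%
    overlap), and each window pair correlated by zero-padded FFT after
    mean removal.  The correlation is normalised per lag by the energy
    of both windows over the overlap region (true normalised cross-
    correlation: a plain circular correlation biases the peak toward
    zero lag on smooth textures, and by Cauchy-Schwarz the normalised
    peak of a purely translated pattern is its exact displacement);
    the search is restricted to lags within a quarter window.  The integer peak is
    refined per axis with a 3-point Gaussian fit; vectors deviating
    from their 3x3 neighbourhood median by more than
    ``outlier_tolerance_px`` (either component) are flagged invalid and
    replaced by that median.  Displacements convert to um/h via the
    pixel size and frame interval (px/frame x um/px x 60/min).
    """
    if frame_a.shape != frame_b.shape:
        raise FrameMismatchError("PIV frames differ in geometry")
    if window_px < 16:
        raise InvalidSpecError("window_px must be >= 16")
    if not (0 <= overlap_fraction < 1):
        raise InvalidSpecError("overlap_fraction must be in [0, 1)")

    foot = _disk_footprint(median_filter_radius_px)
    a = ndimage.median_filter(frame_a.pixels, footprint=foot)
    b = ndimage.median_filter(frame_b.pixels, footprint=foot)

    h, w = a.shape
    stride = max(1, int(round(window_px * (1 - overlap_fraction))))
    n_by = (h - window_px) // stride + 1
    n_bx = (w - window_px) // stride + 1
    if n_by < 1 or n_bx < 1:
        raise InvalidSpecError("frame smaller than one PIV window")

    disp_y = np.zeros((n_by, n_bx))
    disp_x = np.zeros((n_by, n_bx))
    valid = np.ones((n_by, n_bx), dtype=bool)
    max_disp = window_px // 4
    pad = 2 * window_px
    lag = np.fft.fftfreq(pad, 1 / pad).astype(int)
    searchable = (
        (np.abs(lag)[:, None] <= max_disp) & (np.abs(lag)[None, :] <= max_disp)
    )
    mask_f = np.fft.fft2(np.ones((window_px, window_px)), (pad, pad))

    for r in range(n_by):
        for c in range(n_bx):
            wa = a[r * stride : r * stride + window_px, c * stride : c * stride + window_px]
            wb = b[r * stride : r * stride + window_px, c * stride : c * stride + window_px]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            sa, sb = wa.std(), wb.std()
            if sa < 1e-12 or sb < 1e-12:
                valid[r, c] = False
                continue
            fb = np.fft.fft2(wb, (pad, pad))
            num = np.fft.ifft2(np.conj(np.fft.fft2(wa, (pad, pad))) * fb).real
            # per-lag window energies over the overlap region
            e_a = np.fft.ifft2(
                np.conj(np.fft.fft2(wa**2, (pad, pad))) * mask_f
            ).real
            e_b = np.fft.ifft2(np.conj(mask_f) * np.fft.fft2(wb**2, (pad, pad))).real
            denom = np.sqrt(np.maximum(e_a, 0.0) * np.maximum(e_b, 0.0))
            floor = 1e-3 * math.sqrt(float((wa**2).sum() * (wb**2).sum()))
            ncc = np.where(searchable, num / np.maximum(denom, floor), -np.inf)
            peak = np.unravel_index(np.argmax(ncc), ncc.shape)
            dy, dx = int(lag[peak[0]]), int(lag[peak[1]])
            if subpixel:
                sdy, sdx = _subpixel_refine(ncc, peak[0], peak[1])
                dy, dx = dy + sdy, dx + sdx
            disp_y[r, c], disp_x[r, c] = dy, dx

    # local 3x3 median outlier test, applied to raw (px/frame) vectors
    med_y = ndimage.median_filter(disp_y, size=3, mode="nearest")
    med_x = ndimage.median_filter(disp_x, size=3, mode="nearest")
    outlier = (
        (np.abs(disp_y - med_y) > outlier_tolerance_px)
        | (np.abs(disp_x - med_x) > outlier_tolerance_px)
    ) & valid
    disp_y = np.where(outlier | ~valid, med_y, disp_y)
    disp_x = np.where(outlier | ~valid, med_x, disp_x)
    valid = valid & ~outlier

    to_um_h = frame_a.pixel_size_um * 60.0 / frame_interval_min
    return VelocityField(
        u=disp_x * to_um_h,
        v=disp_y * to_um_h,
        valid=valid,
        box_stride_um=stride * frame_a.pixel_size_um,
        n_outliers_replaced=int(outlier.sum()),
    )


def region_motility(
    fieldv: VelocityField, region_boxes_9: list[tuple[int, int]]
) -> tuple[float, int]:
    """Mean speed over a 9-box region (um/h).

    Returns ``(mean_speed, n_originally_invalid)``; infilled outlier
    vectors contribute their replaced values.
    """
    nr, nc = fieldv.shape
    for r, c in region_boxes_9:
        if not (0 <= r < nr and 0 <= c < nc):
            raise RegionOutOfBoundsError(f"box ({r}, {c}) outside field {nr}x{nc}")
    speeds = [fieldv.speed[r, c] for r, c in region_boxes_9]
    n_invalid = sum(0 if fieldv.valid[r, c] else 1 for r, c in region_boxes_9)
    return float(np.mean(speeds)), n_invalid


def field_divergence(
    fieldv: VelocityField,
    region_boxes_9: list[tuple[int, int]] | None = None,
) -> np.ndarray | tuple[np.ndarray, float]:
    """Divergence du/dx + dv/dy of the velocity field, per box (1/h).

    Central differences on the box grid (one-sided at edges), exact for
    linear fields; negative values indicate local convergence
    (condensation).  With ``region_boxes_9`` also returns the region
    mean.
    """
    nr, nc = fieldv.shape
    if nr < 3 or nc < 3:
        raise FieldTooSmallError("need >= 3x3 boxes for divergence")
    s = fieldv.box_stride_um
    du_dx = np.gradient(fieldv.u, s, axis=1)
    dv_dy = np.gradient(fieldv.v, s, axis=0)
    div = du_dx + dv_dy
    if region_boxes_9 is None:
        return div
    for r, c in region_boxes_9:
        if not (0 <= r < nr and 0 <= c < nc):
            raise RegionOutOfBoundsError(f"box ({r}, {c}) outside field {nr}x{nc}")
    return div, float(np.mean([div[r, c] for r, c in region_boxes_9]))


# ---------------------------------------------------------------------------
# primordia tracking


def track_primordia(
    frames: list[ImageFrame],
    threshold_quantile: float = 0.30,
    gaussian_sigma_px: float = 10.0,
    min_area_px: int = 10_000,
    gate_px: float | None = None,
    ap_axis: str = "rows",
) -> list[PrimordiumTrack]:
    """Track detected primordia along the AP axis, recording fusions.

    Each frame is passed through :func:`detect_primordia`; detections in
    consecutive frames are linked greedily by nearest AP-coordinate
    within ``gate_px`` (default 1.5x the mean equivalent blob radius of
    the first detections).  An unmatched detection opens a new track.
    When two tracks compete for one detection the nearer continues and
    the other ends there with a fusion event recorded on the survivor.
    """
    if len(frames) < 2:
        raise InvalidSpecError("need >= 2 frames to track")
    axis = 1 if ap_axis == "rows" else 0  # centroid index: (x, y); y = rows

    detections: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    for f in frames:
        pset = detect_primordia(f, threshold_quantile, gaussian_sigma_px, min_area_px)
        detections.append(pset.centers_px[:, axis] if pset.n else np.zeros(0))
        areas.append(pset.areas_px)

    if gate_px is None:
        for a in areas:
            if len(a):
                gate_px = 1.5 * float(np.mean(np.sqrt(a / np.pi)))
                break
        else:
            return []

    tracks: list[PrimordiumTrack] = []
    active: dict[int, PrimordiumTrack] = {}
    next_id = 0
    for pos in detections[0]:
        tr = PrimordiumTrack(next_id, 0, [float(pos)])
        tracks.append(tr)
        active[next_id] = tr
        next_id += 1

    for k in range(1, len(frames)):
        dets = detections[k]
        pairs = sorted(
            (
                (abs(active[tid].positions_px[-1] - dets[j]), tid, j)
                for tid in active
                for j in range(len(dets))
            ),
            key=lambda t: t[0],
        )
        assigned_tracks: dict[int, int] = {}
        det_owner: dict[int, int] = {}
        for dist, tid, j in pairs:
            if dist > gate_px or tid in assigned_tracks:
                continue
            if j in det_owner:
                continue
            assigned_tracks[tid] = j
            det_owner[j] = tid
        ended = []
        for tid, tr in active.items():
            if tid in assigned_tracks:
                tr.positions_px.append(float(dets[assigned_tracks[tid]]))
                continue
            # unmatched: fusion if its nearest in-gate detection was taken
            dists = np.abs(dets - tr.positions_px[-1]) if len(dets) else np.zeros(0)
            fused = False
            if len(dists):
                j = int(np.argmin(dists))
                if dists[j] <= gate_px and j in det_owner:
                    survivor = active[det_owner[j]]
                    survivor.fusion_events.append((k, tid))
                    tr.ended_by_fusion = True
                    fused = True
            ended.append(tid)
            del fused
        for tid in ended:
            del active[tid]
        for j in range(len(dets)):
            if j not in det_owner:
                tr = PrimordiumTrack(next_id, k, [float(dets[j])])
                tracks.append(tr)
                active[next_id] = tr
                next_id += 1
    return tracks
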