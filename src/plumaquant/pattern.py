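"""Primordia detection and point-pattern statistics.

Detection follows a threshold-based recipe: keep the brightest fraction
of pixels, smooth, binarise, and keep connected components above a
minimum area ("at least" semantics — a component of exactly the minimum
area is retained).  Pattern fidelity is the standard deviation of
neighbour spacings normalised to their mean, either along an ordered
row of primordia or over interior Delaunay edges of a 2D array (edges
touching the convex hull are excluded, since hull vertices have
truncated neighbourhoods).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidPolygonError,
    InvalidRoiError,
    InvalidSpecError,
    NoInteriorEdgesError,
    UnknownLabelError,
)
from .frames import ImageFrame

__all__ = [
    "PrimordiumSet",
    "SpacingStats",
    "detect_primordia",
    "row_spacing_variability",
    "delaunay_spacing_variability",
    "delaunay_interior_edges",
    "primordia_density",
    "primordium_areas",
    "polygon_area_retractation",
]


@dataclass
class PrimordiumSet:
    """Detected primordia as labelled connected components.

    ``labels`` maps each pixel to a component id (0 = background);
    component ids are 1..n, sorted by first (row-major) occurrence.
    Centres are intensity-free centroids of the binary components.
    """

    labels: np.ndarray
    label_ids: np.ndarray
    centers_px: np.ndarray  # (n, 2) as (x, y) pixel coordinates
    centers_um: np.ndarray  # (n, 2) as (x, y) micrometres
    areas_px: np.ndarray
    pixel_size_um: float

    @property
    def n(self) -> int:
        return len(self.label_ids)

    def area_mm2(self, label: int) -> float:
        """Area of one component in mm^2."""
        hits = np.nonzero(self.label_ids == label)[0]
        if len(hits) == 0:
            raise UnknownLabelError(f"no component with label {label}")
        return float(
            self.areas_px[hits[0]] * self.pixel_size_um**2 * 1e-6
        )

    @property
    def areas_mm2(self) -> np.ndarray:
        return self.areas_px * self.pixel_size_um**2 * 1e-6


@dataclass
class SpacingStats:
    """Neighbour-spacing variability of a primordia pattern.

    ``spacing_variability`` is the sample standard deviation of the
    used neighbour distances divided by their mean — dimensionless,
    zero for a perfectly regular pattern.
    """

    distances_um: np.ndarray
    mean_um: float
    sd_um: float
    spacing_variability: float
    n_edges_used: int
    n_edges_excluded: int


def detect_primordia(
    frame: ImageFrame,
    threshold_quantile: float = 0.30,
    gaussian_sigma_px: float = 10.0,
    min_area_px: int = 10_000,
) -> PrimordiumSet:
    """Threshold-based primordia detection.

    Steps: (1) keep the ``threshold_quantile`` brightest pixels
    (nearest-rank quantile of all frame intensities; the default 0.30
    keeps the 30% brightest) and zero the rest; (2) Gaussian-smooth
    the thresholded image with ``gaussian_sigma_px`` (0 skips
    smoothing); (3) binarise at half the mean of the retained nonzero
    intensities; (4) label 8-connected components; (5) keep components
    with area >= ``min_area_px`` (inclusive).

    Component centres are centroids weighted by the smoothed intensity
    in excess of the binarisation level, anchoring them to the bright
    condensation core rather than the dimmer halo of the binarised
    footprint.  A constant frame yields an empty set.
    """
    if not (0 < threshold_quantile < 1):
        raise InvalidSpecError("threshold_quantile must be in (0, 1)")
    if min_area_px < 1:
        raise InvalidSpecError("min_area_px must be >= 1")
    img = frame.pixels
    flat = np.sort(img.ravel())
    rank = int(np.ceil((1 - threshold_quantile) * flat.size)) - 1
    threshold = flat[max(rank, 0)]
    kept = np.where(img >= threshold, img, 0.0)
    retained = kept[kept > 0]
    if retained.size == 0:  # constant or all-zero frame
        empty = np.zeros(img.shape, dtype=int)
        z = np.zeros((0, 2))
        return PrimordiumSet(
            empty, np.zeros(0, dtype=int), z, z, np.zeros(0, dtype=int),
            frame.pixel_size_um,
        )
    smoothed = (
        ndimage.gaussian_filter(kept, gaussian_sigma_px)
        if gaussian_sigma_px > 0
        else kept
    )
    level = 0.5 * retained.mean()
    binary = smoothed >= level
    labels, n_raw = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))

    ids, centers_px, areas = [], [], []
    if n_raw:
        counts = np.bincount(labels.ravel())
        excess = np.maximum(smoothed - level, 0.0)
        keep_id = 1
        relabel = np.zeros(n_raw + 1, dtype=int)
        for lab in range(1, n_raw + 1):
            if counts[lab] >= min_area_px:
                relabel[lab] = keep_id
                ids.append(keep_id)
                yy, xx = np.nonzero(labels == lab)
                w = excess[yy, xx]
                wsum = w.sum()
                if wsum > 0:
                    cy, cx = float((w * yy).sum() / wsum), float((w * xx).sum() / wsum)
                else:  # flat plateau exactly at the level
                    cy, cx = float(yy.mean()), float(xx.mean())
                centers_px.append((cx, cy))
                areas.append(int(counts[lab]))
                keep_id += 1
        labels = relabel[labels]
    centers_px = np.asarray(centers_px, dtype=float).reshape(-1, 2)
    return PrimordiumSet(
        labels,
        np.asarray(ids, dtype=int),
        centers_px,
        centers_px * frame.pixel_size_um,
        np.asarray(areas, dtype=int),
        frame.pixel_size_um,
    )


def _spacing_stats(distances: np.ndarray, n_excluded: int = 0) -> SpacingStats:
    mean = float(distances.mean())
    sd = float(distances.std(ddof=1))
    return SpacingStats(
        distances_um=distances,
        mean_um=mean,
        sd_um=sd,
        spacing_variability=sd / mean,
        n_edges_used=len(distances),
        n_edges_excluded=n_excluded,
    )


def row_spacing_variability(ordered_centers_um: np.ndarray) -> SpacingStats:
    """Spacing variability along an ordered row of primordia.

    Distances are Euclidean gaps between consecutive centres; the
    statistic is their sample standard deviation (n-1 denominator)
    divided by their mean.  Needs >= 3 centres (2 gaps).
    """
    pts = np.asarray(ordered_centers_um, dtype=float)
    if len(pts) < 3:
        raise InsufficientPointsError("need >= 3 centers for a row statistic")
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return _spacing_stats(gaps)


def delaunay_interior_edges(
    centers_um: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Interior Delaunay edges of a point set.

    Returns ``(points_sorted, edges, n_excluded)`` where ``edges`` is an
    (m, 2) array of index pairs into the lexicographically sorted point
    array, keeping only edges with neither endpoint on the convex hull
    boundary.  A point counts as boundary if it lies on any hull facet
    (within a relative tolerance), not only if it is a hull vertex —
    collinear points on a straight hull edge are boundary points too.
    Input points are sorted lexicographically first so co-circular
    tie-breaks are reproducible regardless of input order.
    """
    pts = np.asarray(centers_um, dtype=float)
    if len(pts) < 4:
        raise DegenerateGeometryError("need >= 4 points to triangulate")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    try:
        tri = Delaunay(pts)
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points collinear")
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = sorted((simplex[a], simplex[b]))
            edges.add((i, j))
    # signed distance of every point to each hull facet; ~0 => on boundary
    dists = pts @ hull.equations[:, :2].T + hull.equations[:, 2][None, :]
    scale = float(np.abs(pts).max()) or 1.0
    on_facet = np.any(np.abs(dists) <= 1e-9 * scale, axis=1)
    boundary = set(hull.vertices.tolist()) | set(np.nonzero(on_facet)[0].tolist())
    used = np.array(
        sorted(e for e in edges if e[0] not in boundary and e[1] not in boundary),
        dtype=int,
    ).reshape(-1, 2)
    return pts, used, len(edges) - len(used)


def delaunay_spacing_variability(centers_um: np.ndarray) -> SpacingStats:
    """Spacing variability over interior Delaunay edges.

    The Delaunay triangulation defines neighbour pairs; edges with a
    vertex on the convex hull are excluded (their neighbourhoods are
    truncated by the field of view).  The statistic is the sample sd of
    the remaining edge lengths divided by their mean.
    """
    pts, used, n_excl = delaunay_interior_edges(centers_um)
    if len(used) == 0:
        raise NoInteriorEdgesError("all triangulation vertices lie on the hull")
    d = np.linalg.norm(pts[used[:, 0]] - pts[used[:, 1]], axis=1)
    if len(d) < 2:
        raise InsufficientPointsError("need >= 2 interior edges for an sd")
    return _spacing_stats(d, n_excl)


def primordia_density(
    pset_or_centers: PrimordiumSet | np.ndarray,
    roi_mm: tuple[float, float, float, float],
) -> float:
    """Primordia count per mm^2 inside a rectangular ROI.

    ``roi_mm`` is (x0, y0, width, height) in millimetres.  The rectangle
    is half-open: a centre on a low-coordinate edge counts, one on a
    high-coordinate edge does not — every centre lands in exactly one
    tile of a tiling.
    """
    x0, y0, w, h = roi_mm
    if w <= 0 or h <= 0:
        raise InvalidRoiError("roi must have positive area")
    centers_um = (
        pset_or_centers.centers_um
        if isinstance(pset_or_centers, PrimordiumSet)
        else np.asarray(pset_or_centers, dtype=float)
    )
    if len(centers_um) == 0:
        return 0.0
    c_mm = centers_um / 1000.0
    inside = (
        (c_mm[:, 0] >= x0)
        & (c_mm[:, 0] < x0 + w)
        & (c_mm[:, 1] >= y0)
        & (c_mm[:, 1] < y0 + h)
    )
    return float(inside.sum() / (w * h))


def primordium_areas(pset: PrimordiumSet) -> np.ndarray:
    """Component areas in mm^2 (pixel count x pixel area x 1e-6)."""
    return pset.areas_mm2


def _polygon_is_simple(v: np.ndarray) -> bool:
    """Check that no two non-adjacent polygon edges intersect."""
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = cross(p3, p4, p1), cross(p3, p4, p2)
            d3, d4 = cross(p1, p2, p3), cross(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return False
    return True


def polygon_area_retractation(
    outline_t0_mm: np.ndarray,
    outline_t1_mm: np.ndarray,
) -> tuple[float, float, float]:
    """Explant surface-area change between two manually outlined stages.

    Areas are computed with the shoelace formula (absolute value);
    returns ``(area_t0, area_t1, retractation_percent)`` where the
    retractation is ``100 * (1 - area_t1 / area_t0)`` — positive when
    the explant shrank.
    """

    def shoelace(v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise InvalidPolygonError("outline needs >= 3 (x, y) vertices")
        if not _polygon_is_simple(v):
            raise InvalidPolygonError("outline is self-intersecting")
        x, y = v[:, 0], v[:, 1]
        return float(
            0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        )

    a0 = shoelace(outline_t0_mm)
    a1 = shoelace(outline_t1_mm)
    if a0 == 0:
        raise InvalidPolygonError("initial outline has zero area")
    return a0, a1, 100.0 * (1.0 - a1 / a0)
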