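"""Readers, writers and run configuration.

All physical outputs are in micrometres / mm^2 / um h^-1; pixel
quantities appear only in audit columns.  Every run can write its fully
resolved configuration next to its outputs so published numbers are
reproducible byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .anisotropy import AnisotropyMap
from .errors import FormatError, InvalidSpecError, IoError, UnsupportedChannelsError
from .frames import ImageFrame
from .pattern import PrimordiumSet, SpacingStats
from .timelapse import PrimordiumTrack

__all__ = [
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "read_centers_csv",
    "write_centers_csv",
    "write_anisotropy_csv",
    "write_primordia_csv",
    "write_spacing_csv",
    "write_tracks_csv",
    "write_config_json",
]


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    pixel_size_um: float = 0.5
    frame_interval_min: float = 5.0
    box_size_um: float = 25.0
    overlap_fraction: float = 0.5
    threshold_quantile: float = 0.30
    gaussian_sigma_px: float = 10.0
    min_area_px: int = 10_000
    ap_axis: str = "rows"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise InvalidSpecError("physical quantities must be > 0")
        if self.box_size_um <= 0:
            raise InvalidSpecError("box_size_um must be > 0")
        if not (0 < self.threshold_quantile < 1):
            raise InvalidSpecError("threshold_quantile must be in (0, 1)")
        if self.ap_axis not in ("rows", "cols"):
            raise InvalidSpecError("ap_axis must be 'rows' or 'cols'")


def read_image_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float = 5.0,
) -> list[ImageFrame]:
    """Read a single- or multi-page grayscale TIFF as ordered frames.

    Page k gets timestamp ``k * frame_interval_min``.  RGB pages are
    rejected: split channels upstream and pass one grayscale stack per
    channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"not a readable TIFF: {path} ({exc})") from exc
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise UnsupportedChannelsError(
            "expected grayscale pages; got shape "
            f"{arr.shape} — pre-split channels into separate stacks"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise UnsupportedChannelsError(
            "RGB(A) pages are not supported — pre-split channels"
        )
    return [
        ImageFrame(
            arr[k].astype(float), pixel_size_um, timestamp_min=k * frame_interval_min
        )
        for k in range(arr.shape[0])
    ]


def write_image_stack(path: str | Path, frames: list[ImageFrame]) -> None:
    """Write frames as a 16-bit multi-page TIFF (one page per frame)."""
    stack = np.stack([f.pixels for f in frames])
    lo, hi = stack.min(), stack.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(
        str(path), ((stack - lo) * scale).astype(np.uint16), photometric="minisblack"
    )


def read_centers_csv(path: str | Path) -> np.ndarray:
    """Centres CSV (columns x_um, y_um) -> (n, 2) array."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"x_um", "y_um"}.issubset(df.columns):
        raise FormatError("centers CSV needs columns x_um, y_um")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def write_centers_csv(
    path: str | Path, centers_um: np.ndarray, flags: list[str] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "x_um": np.asarray(centers_um).reshape(-1, 2)[:, 0],
            "y_um": np.asarray(centers_um).reshape(-1, 2)[:, 1],
            "flag": flags if flags is not None else [""] * len(centers_um),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_anisotropy_csv(path: str | Path, amap: AnisotropyMap) -> None:
    """Per-box anisotropy table (positions in um, angle in degrees)."""
    rows = []
    for r in range(amap.shape[0]):
        for c in range(amap.shape[1]):
            x, y = amap.grid.box_center_um(r, c)
            rows.append(
                {
                    "box_row": r,
                    "box_col": c,
                    "center_x_um": x,
                    "center_y_um": y,
                    "amplitude": amap.amplitude[r, c],
                    "angle_deg": np.degrees(amap.angle_rad[r, c]),
                    "degenerate": bool(amap.degenerate[r, c]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_primordia_csv(path: str | Path, pset: PrimordiumSet) -> None:
    pd.DataFrame(
        {
            "label": pset.label_ids,
            "x_um": pset.centers_um[:, 0] if pset.n else [],
            "y_um": pset.centers_um[:, 1] if pset.n else [],
            "area_px": pset.areas_px,
            "area_mm2": pset.areas_mm2,
        }
    ).to_csv(path, index=False)


def write_spacing_csv(path: str | Path, stats: SpacingStats) -> None:
    pd.DataFrame(
        [
            {
                "mean_um": stats.mean_um,
                "sd_um": stats.sd_um,
                "spacing_variability": stats.spacing_variability,
                "n_edges_used": stats.n_edges_used,
                "n_edges_excluded": stats.n_edges_excluded,
            }
        ]
    ).to_csv(path, index=False)


def write_tracks_csv(path: str | Path, tracks: list[PrimordiumTrack]) -> None:
    rows = []
    for tr in tracks:
        fusion_frames = {f: tid for f, tid in tr.fusion_events}
        for k, pos in enumerate(tr.positions_px):
            frame = tr.start_frame + k
            event = ""
            if frame in fusion_frames:
                event = f"fusion_absorbed_{fusion_frames[frame]}"
            elif frame == tr.end_frame and tr.ended_by_fusion:
                event = "ended_by_fusion"
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frame,
                    "ap_position_px": pos,
                    "event": event,
                }
            )
    cols = ["track_id", "frame", "ap_position_px", "event"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_config_json(path: str | Path, config: RunConfig) -> None:
    out = Path(path)
    try:
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise IoError(f"cannot write {out}: {exc}") from exc
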