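"""Displacement, regional and explant-morphology statistics.

Post-processing of bead trajectories (tracked or synthetic) and explant
outlines into the summary quantities used to compare gel remodeling between
boundary-condition cases: cumulative displacement from the initial frame,
instantaneous frame-to-frame rates, period-average rates over multi-hour
windows, per-region means, and explant area / centroid-distance ratios.

"Cumulative displacement" is the net displacement from the first frame (the
Euclidean norm of ``position_t - position_0``), not the accumulated path
length; with this definition the per-window period-average rates telescope
to the final cumulative displacement.  Path-length accumulation is available
behind ``path_length=True`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "Trajectory",
    "RegionMap",
    "displacement_stats",
    "trajectory_frame",
    "regional_summary",
    "explant_morphology",
    "default_region_map",
    "assign_region",
]


@dataclass
class Trajectory:
    """Single-bead position series.

    ``positions``: (n_frames, 2) in micrometres (or pixels with the scale
    tracked by the caller); ``frame_interval``: minutes between frames;
    ``region``: spatial region label 1-4 (0 = unassigned).
    """

    id: int
    positions: np.ndarray
    frame_interval: float = 15.0
    region: int = 0
    scores: np.ndarray | None = None  # per-step tracker correlation
    lost_from: int | None = None  # frame index where tracking was lost

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_frames, 2) array")
        if len(self.positions) < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def displacement_stats(
    traj: Trajectory, window_min: float = 360.0, path_length: bool = False
) -> dict[str, np.ndarray]:
    """Cumulative displacement and displacement-rate series of one bead.

    Returns ``cumulative`` (per frame, same units as positions),
    ``instantaneous_rate`` (per frame step, units/min, displacement between
    successive frames over the frame interval) and ``period_rate`` (one value
    per ``window_min`` window: the change in cumulative displacement over the
    window divided by the window duration in minutes).
    """
    if traj.n_frames < 2:
        raise ValueError("displacement statistics need at least two frames")
    steps = np.diff(traj.positions, axis=0)
    step_norms = np.linalg.norm(steps, axis=1)
    if path_length:
        cumulative = np.concatenate([[0.0], np.cumsum(step_norms)])
    else:
        cumulative = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
    inst_rate = step_norms / traj.frame_interval

    frames_per_window = window_min / traj.frame_interval
    if abs(frames_per_window - round(frames_per_window)) > 1e-9:
        raise ValueError(
            f"window of {window_min} min is not a whole number of "
            f"{traj.frame_interval}-min frames"
        )
    fpw = int(round(frames_per_window))
    n_windows = (traj.n_frames - 1) // fpw
    ends = np.arange(n_windows + 1) * fpw
    period_rate = np.diff(cumulative[ends]) / window_min
    return {
        "cumulative": cumulative,
        "instantaneous_rate": inst_rate,
        "period_rate": period_rate,
    }


def trajectory_frame(trajectories) -> pd.DataFrame:
    """Long-format table (bead, frame, x, y, region) of many trajectories."""
    rows = []
    for t in trajectories:
        for f, (x, y) in enumerate(t.positions):
            rows.append((t.id, f, x, y, t.region))
    return pd.DataFrame(rows, columns=["bead", "frame", "x", "y", "region"])


@dataclass
class RegionMap:
    """Tile-grid to region assignment over the imaged field.

    ``grid`` is an (n_rows, n_cols) integer array of region labels 1-4;
    tile (0, 0) is the upper-left image tile.
    """

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=int)
        present = set(np.unique(self.grid).tolist())
        if not present <= {1, 2, 3, 4}:
            raise ValueError("region labels must be in {1, 2, 3, 4}")
        if present != {1, 2, 3, 4}:
            raise ValueError("all four regions must be non-empty")

    def to_text(self) -> str:
        """Whitespace grid serialization (one tile row per line)."""
        return "\n".join(" ".join(str(v) for v in row) for row in self.grid) + "\n"

    @staticmethod
    def from_text(text: str) -> "RegionMap":
        rows = [
            [int(v) for v in line.split()]
            for line in text.strip().splitlines()
            if line.strip()
        ]
        return RegionMap(np.array(rows))


def default_region_map() -> RegionMap:
    """Default 6x6 tiling: region 1 above the explants, 2 lateral, 3 axial
    and central (between the explants), 4 below."""
    g = np.full((6, 6), 3, dtype=int)
    g[0, :] = 1
    g[5, :] = 4
    g[1:5, 0] = 2
    g[1:5, 5] = 2
    return RegionMap(g)


def assign_region(
    position, field_shape: tuple[float, float], region_map: RegionMap
) -> int:
    """Region of a point: ``position`` (x, y) with y measured downward
    (image convention); ``field_shape`` = (width, height) in the same units."""
    x, y = position
    n_rows, n_cols = region_map.grid.shape
    col = min(int(x / field_shape[0] * n_cols), n_cols - 1)
    row = min(int(y / field_shape[1] * n_rows), n_rows - 1)
    if x < 0 or y < 0 or col < 0 or row < 0:
        raise ValueError("position outside the imaged field")
    return int(region_map.grid[row, col])


def regional_summary(
    trajectories, region_map: RegionMap | None = None,
    field_shape: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-region mean +/- SD of cumulative displacement at every frame.

    Trajectories must carry region labels; alternatively pass ``region_map``
    and ``field_shape`` to label them from their initial positions.  Rows
    with region 0 (``overall``) pool all beads.  Empty regions are excluded
    with a warning column rather than an error.
    """
    trajs = list(trajectories)
    if region_map is not None:
        if field_shape is None:
            raise ValueError("field_shape is required with a region map")
        for t in trajs:
            t.region = assign_region(t.positions[0], field_shape, region_map)
    if any(t.region == 0 for t in trajs):
        raise ValueError("all trajectories must be region-labeled")
    n_frames = min(t.n_frames for t in trajs)
    cum = np.stack(
        [displacement_stats(t)["cumulative"][:n_frames] for t in trajs]
    )
    regions = np.array([t.region for t in trajs])
    rows = []
    for reg in (1, 2, 3, 4):
        sel = regions == reg
        if not np.any(sel):
            continue
        for f in range(n_frames):
            rows.append(
                (reg, f, cum[sel, f].mean(), cum[sel, f].std(ddof=0), int(sel.sum()))
            )
    for f in range(n_frames):
        rows.append((0, f, cum[:, f].mean(), cum[:, f].std(ddof=0), len(trajs)))
    return pd.DataFrame(rows, columns=["region", "frame", "mean", "sd", "n"])


def explant_morphology(outlines) -> pd.DataFrame:
    """Area, centroid and normalized morphology series of one explant.

    ``outlines``: per-time explant outline, each either a boolean mask
    ``(mask, pixel_size)`` tuple (area = pixel count * pixel_size^2) or a
    shapely ``Polygon`` / (n, 2) coordinate array.  Returns a table with
    area, area ratio vs the first time point, and centroid coordinates.
    """
    areas, cxs, cys = [], [], []
    for out in outlines:
        if isinstance(out, tuple):
            mask, pixel_size = out
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError("empty explant mask")
            areas.append(mask.sum() * pixel_size**2)
            rows, cols = np.nonzero(mask)
            cxs.append(cols.mean() * pixel_size)
            cys.append(rows.mean() * pixel_size)
        else:
            poly = out if isinstance(out, Polygon) else Polygon(np.asarray(out))
            if poly.is_empty or poly.area == 0:
                raise ValueError("empty explant outline")
            areas.append(poly.area)
            cxs.append(poly.centroid.x)
            cys.append(poly.centroid.y)
    areas = np.asarray(areas)
    return pd.DataFrame(
        {
            "time_index": np.arange(len(areas)),
            "area": areas,
            "area_ratio": areas / areas[0],
            "centroid_x": cxs,
            "centroid_y": cys,
        }
    )
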