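"""Grid-averaged cell-migration vector fields from time-lapse trajectories.

Input is a track table (one row per labeled cell per frame, positions in µm
in the embryo plane, +y pointing posterior).  Per-cell velocity at a frame
is the central difference over the flanking frames, i.e. averaged over
three consecutive frames; the field is the arithmetic mean of those
velocities over the cells lying within a fixed radius of each point of a
square grid (default 150 µm spacing and 150 µm radius).  Velocities are
reported in µm/h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("cell_id", "group", "frame", "t_min", "x_um", "y_um")


@dataclass(frozen=True)
class VelocityField:
    """Grid-anchored mean migration vectors.

    ``table`` has one row per grid point with columns gx, gy (µm), vx, vy
    (µm/h), speed (µm/h) and n (contributing cells); rows with n == 0 carry
    NaN vectors.
    """

    table: pd.DataFrame
    spacing: float
    radius: float
    center_frame: int

    @property
    def populated(self) -> pd.DataFrame:
        return self.table[self.table["n"] > 0]


def _frame_interval(track: pd.DataFrame) -> float:
    t = np.sort(track["t_min"].unique())
    if len(t) < 2:
        raise ValueError("track table must span at least two frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("frames must be uniformly spaced in time")
    return float(dt[0])


def cell_velocity(
    track: pd.DataFrame, center_frame: int, frame_interval_min: float | None = None
) -> np.ndarray | None:
    """Central-difference velocity (µm/h) of one cell at ``center_frame``.

    The velocity is the displacement between the frames 1 before and
    1 after the center, divided by twice the frame interval — i.e. the
    mean velocity over the three consecutive frames.  Returns None when a
    flanking frame is missing.
    """
    if frame_interval_min is None:
        frame_interval_min = _frame_interval(track)
    by_frame = track.set_index("frame")
    try:
        before = by_frame.loc[center_frame - 1, ["x_um", "y_um"]].to_numpy(float)
        after = by_frame.loc[center_frame + 1, ["x_um", "y_um"]].to_numpy(float)
    except KeyError:
        return None
    return (after - before) / (2.0 * frame_interval_min) * 60.0


def _velocities_at(
    tracks: pd.DataFrame, center_frame: int, groups: list[str] | None = None
) -> pd.DataFrame:
    """One row per cell with a complete frame triple: position + velocity."""
    sub = tracks[tracks["frame"].isin([center_frame - 1, center_frame, center_frame + 1])]
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    dt = _frame_interval(tracks)
    rows = []
    skipped = 0
    for cell, cell_rows in sub.groupby("cell_id", sort=False):
        by_frame = cell_rows.set_index("frame")
        if not {center_frame - 1, center_frame, center_frame + 1} <= set(by_frame.index):
            skipped += 1
            continue
        p0 = by_frame.loc[center_frame, ["x_um", "y_um"]].to_numpy(float)
        v = (
            by_frame.loc[center_frame + 1, ["x_um", "y_um"]].to_numpy(float)
            - by_frame.loc[center_frame - 1, ["x_um", "y_um"]].to_numpy(float)
        ) / (2.0 * dt) * 60.0
        rows.append((cell, by_frame["group"].iloc[0], p0[0], p0[1], v[0], v[1]))
    if skipped:
        logger.info(
            "excluded %d cell(s) lacking a complete frame triple at frame %d",
            skipped, center_frame,
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "group", "x_um", "y_um", "vx", "vy"]
    )


def grid_field(
    tracks: pd.DataFrame,
    center_frame: int,
    spacing: float = 150.0,
    radius: float = 150.0,
    groups: list[str] | None = None,
) -> VelocityField:
    """Average per-cell velocities over grid-point-centered circles.

    Each cell contributes its single three-frame velocity once to every
    grid point whose circle (inclusive boundary) contains the cell's
    center-frame position.  The grid is anchored at the bounding-box
    minimum rounded down to a multiple of the spacing.
    """
    if spacing <= 0 or radius <= 0:
        raise ValueError("grid spacing and radius must be positive")
    cells = _velocities_at(tracks, center_frame, groups=groups)
    if cells.empty:
        raise ValueError(f"no cell has a complete frame triple at frame {center_frame}")

    pos = cells[["x_um", "y_um"]].to_numpy()
    lo = np.floor(pos.min(axis=0) / spacing) * spacing
    hi = np.ceil(pos.max(axis=0) / spacing) * spacing
    gx = np.arange(lo[0], hi[0] + spacing / 2, spacing)
    gy = np.arange(lo[1], hi[1] + spacing / 2, spacing)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    grid = np.column_stack([GX.ravel(), GY.ravel()])

    vel = cells[["vx", "vy"]].to_numpy()
    d2 = ((grid[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    member = d2 <= radius**2
    n = member.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_v = (member.astype(float) @ vel) / np.where(n > 0, n, 1)[:, None]
    mean_v[n == 0] = np.nan

    table = pd.DataFrame(
        {
            "gx": grid[:, 0],
            "gy": grid[:, 1],
            "vx": mean_v[:, 0],
            "vy": mean_v[:, 1],
            "speed": np.hypot(mean_v[:, 0], mean_v[:, 1]),
            "n": n,
        }
    )
    return VelocityField(table=table, spacing=spacing, radius=radius, center_frame=center_frame)


@dataclass(frozen=True)
class SpeedSummary:
    """Group migration-speed statistics over a frame range."""

    group: str
    n_cells: int
    mean_speed: float  # µm/h
    sd_speed: float  # sample SD, µm/h
    posterior_fraction: float  # cells with |vy| > |vx| and vy > 0


def speed_summary(
    tracks: pd.DataFrame, group: str, frame_range: tuple[int, int] | None = None
) -> SpeedSummary:
    """Mean ± SD migration speed of a cell group, plus the fraction of cells
    migrating posterior-dominantly (mean velocity with |vy| > |vx|, vy > 0).

    Per-cell speed is the mean of the three-frame velocity magnitudes over
    the center frames in ``frame_range`` (inclusive; default all interior
    frames).
    """
    sub = tracks[tracks["group"] == group]
    if sub.empty:
        raise ValueError(f"no cells in group {group!r}")
    frames = np.sort(sub["frame"].unique())
    if frame_range is None:
        centers = frames[1:-1]
    else:
        centers = [f for f in range(frame_range[0], frame_range[1] + 1) if f in frames]
    if len(centers) == 0:
        raise ValueError("frame range contains no usable center frame")

    dt = _frame_interval(tracks)
    speeds, mean_vs = [], []
    for _, cell_rows in sub.groupby("cell_id", sort=False):
        vs = [cell_velocity(cell_rows, f, frame_interval_min=dt) for f in centers]
        vs = [v for v in vs if v is not None]
        if not vs:
            continue
        vs = np.array(vs)
        speeds.append(np.linalg.norm(vs, axis=1).mean())
        mean_vs.append(vs.mean(axis=0))
    if len(speeds) < 2:
        raise ValueError("need at least two cells with measurable velocities")
    speeds = np.array(speeds)
    mean_vs = np.array(mean_vs)
    posterior = (np.abs(mean_vs[:, 1]) > np.abs(mean_vs[:, 0])) & (mean_vs[:, 1] > 0)
    return SpeedSummary(
        group=group,
        n_cells=len(speeds),
        mean_speed=float(speeds.mean()),
        sd_speed=float(speeds.std(ddof=1)),
        posterior_fraction=float(posterior.mean()),
    )
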