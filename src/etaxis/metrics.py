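"""Cell-centric electrotaxis statistics.

The three headline indices of an electrotaxis experiment:

* **directedness** — mean over cells of cos Φ_i, where Φ_i is the angle
  between a cell's net (first-to-last frame, Euclidean) displacement and
  the applied field vector taken anode→cathode.  +1 for a uniformly
  cathodal cohort, −1 for anodal, 0 in expectation for random migration.
* **speed** — net Euclidean displacement divided by elapsed time, μm/h.
* **orientation index** — mean of cos 2θ_i, where θ_i is the angle
  between a cell's long axis and the field vector.  −1 for perpendicular
  alignment, +1 for parallel, 0 for random; the factor of two makes the
  index well defined for axial (undirected) angles.

Group values are returned with per-cell values and N so confidence
intervals remain computable downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, EmptyGroupError, UndefinedSpeedError
from .io_tracks import RegionMeasure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "FieldVector",
    "GroupMetric",
    "directedness",
    "speed",
    "orientation_index",
    "mean_area",
    "directedness_time_series",
    "orientation_time_series",
    "metrics_table",
]


@dataclass(frozen=True)
class FieldVector:
    """Applied DC electric field: unit anode→cathode direction + strength.

    The direction defines the zero angle of every directional statistic.
    """

    direction: tuple[float, float] = (1.0, 0.0)
    strength: float = 0.0  # V/m
    on_time: float = 0.0  # hours since field on

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.hypot(*d))
        if not math.isfinite(n) or n == 0.0:
            raise ValueError("field direction must be a nonzero 2-vector")
        if abs(n - 1.0) > 1e-9:
            d = d / n
        if self.strength < 0:
            raise ValueError("field strength must be >= 0")
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))

    @property
    def angle(self) -> float:
        """Angle of the anode→cathode direction from +x, radians."""
        return math.atan2(self.direction[1], self.direction[0])


@dataclass(frozen=True)
class GroupMetric:
    """A group statistic together with its per-cell values and N."""

    value: float
    per_cell: np.ndarray
    n: int
    n_excluded: int = 0


def _net_displacements(trajectories: Sequence[Trajectory]) -> np.ndarray:
    return np.array([tr.net_displacement for tr in trajectories], dtype=float)


def directedness(
    trajectories: Sequence[Trajectory], field: FieldVector
) -> GroupMetric:
    """Mean cos Φ_i over cells; Φ_i between net displacement and field.

    Cells with exactly zero net displacement have an undefined angle and
    are excluded with a logged count.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise EmptyGroupError("directedness of an empty cohort")
    disp = _net_displacements(trajectories)
    norms = np.hypot(disp[:, 0], disp[:, 1])
    moving = norms > 0.0
    n_excluded = int((~moving).sum())
    if n_excluded:
        logger.warning("%d cell(s) with zero net displacement excluded "
                       "from directedness", n_excluded)
    if not moving.any():
        raise EmptyGroupError("all cells have zero net displacement")
    d = np.asarray(field.direction)
    cos_phi = (disp[moving] @ d) / norms[moving]
    cos_phi = np.clip(cos_phi, -1.0, 1.0)
    return GroupMetric(float(cos_phi.mean()), cos_phi, int(moving.sum()), n_excluded)


def speed(trajectory: Trajectory) -> float:
    """Net-displacement speed: |r(T) − r(0)| / (T − 0), μm/h."""
    dt = trajectory.elapsed_hours
    if dt <= 0:
        raise UndefinedSpeedError(f"cell {trajectory.cell_id}: no elapsed time")
    return float(np.hypot(*trajectory.net_displacement)) / dt


def orientation_index(
    axis_angles: Iterable[float], field: FieldVector
) -> GroupMetric:
    """Mean cos 2θ_i for long-axis angles θ_i relative to the field.

    ``axis_angles`` are absolute axial angles in radians (from +x);
    entries that are None/NaN (degenerate regions) must be excluded by
    the caller.  The doubling maps the undirected axis onto the circle,
    so parallel ↦ +1, perpendicular ↦ −1 regardless of axis sign.
    """
    ang = np.asarray([a for a in axis_angles], dtype=float)
    if ang.size == 0:
        raise EmptyGroupError("orientation index of an empty angle set")
    if not np.all(np.isfinite(ang)):
        raise ValueError("axis angles must be finite; filter degenerates upstream")
    theta = ang - field.angle
    cos2 = np.cos(2.0 * theta)
    return GroupMetric(float(cos2.mean()), cos2, int(ang.size))


def mean_area(region_measures: Iterable[RegionMeasure | float]) -> float:
    """Mean cell area over regions, μm²."""
    areas = np.asarray(
        [r.area if isinstance(r, RegionMeasure) else float(r)
         for r in region_measures], dtype=float)
    if areas.size == 0:
        raise EmptyGroupError("mean area of an empty collection")
    return float(areas.mean())


def _common_frame_grid(trajectories: Sequence[Trajectory]) -> np.ndarray:
    grids = [np.round(tr.times, 9) for tr in trajectories]
    ref = grids[0]
    for g in grids[1:]:
        if g.size != ref.size or not np.allclose(g, ref, atol=1e-9):
            raise AlignmentError("trajectories do not share a common frame grid; "
                                 "apply the completeness filter first")
    return ref


def directedness_time_series(
    trajectories: Sequence[Trajectory], field: FieldVector
) -> tuple[np.ndarray, np.ndarray]:
    """Group directedness per frame using origin-to-frame displacement.

    Returns (times, values); frame 0 is omitted (zero displacement,
    undefined angle).  Cells whose cumulative displacement is zero at a
    given frame are excluded at that frame only.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise EmptyGroupError("time series of an empty cohort")
    times = _common_frame_grid(trajectories)
    pos = np.stack([tr.positions for tr in trajectories])  # (cells, T, 2)
    disp = (pos - pos[:, :1, :])[:, 1:, :]  # frame 0 omitted: no displacement
    norms = np.hypot(disp[..., 0], disp[..., 1])
    d = np.asarray(field.direction)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_phi = (disp @ d) / norms
    values = np.nanmean(np.where(norms > 0, cos_phi, np.nan), axis=0)
    return times[1:], values


def orientation_time_series(
    region_measures: Iterable[RegionMeasure], field: FieldVector
) -> tuple[np.ndarray, np.ndarray]:
    """Group orientation index per frame from a region-measure stream.

    Degenerate regions (no defined axis) are excluded frame-wise.
    """
    by_frame: dict[int, list[float]] = {}
    for rm in region_measures:
        if rm.axis_angle is not None and not rm.axis_degenerate:
            by_frame.setdefault(rm.frame_index, []).append(rm.axis_angle)
    if not by_frame:
        raise EmptyGroupError("no defined axis angles in any frame")
    frames = np.array(sorted(by_frame), dtype=int)
    values = np.array([
        orientation_index(by_frame[f], field).value for f in frames
    ])
    return frames, values


def metrics_table(
    trajectories: Sequence[Trajectory],
    field: FieldVector,
    axis_angles: dict[str, float] | None = None,
    areas: dict[str, float] | None = None,
):
    """Per-cell metrics as a pandas DataFrame.

    Columns: cell_id, condition, cos_phi (NaN when net displacement is
    zero), speed, net_distance, path_length, path_speed (auxiliary
    total-path-length rate), and cos_2theta / area where provided.
    """
    import pandas as pd

    rows = []
    d = np.asarray(field.direction)
    for tr in trajectories:
        disp = tr.net_displacement
        net = float(np.hypot(*disp))
        cos_phi = float(disp @ d / net) if net > 0 else np.nan
        aa = (axis_angles or {}).get(tr.cell_id)
        rows.append({
            "cell_id": tr.cell_id,
            "condition": tr.condition,
            "cos_phi": cos_phi,
            "speed": speed(tr),
            "net_distance": net,
            "path_length": tr.path_length,
            "path_speed": tr.path_length / tr.elapsed_hours,
            "cos_2theta": (math.cos(2 * (aa - field.angle))
                           if aa is not None else np.nan),
            "area": (areas or {}).get(tr.cell_id, np.nan),
        })
    return pd.DataFrame(rows)
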