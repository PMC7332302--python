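"""Track-table and label-mask input/output.

Trajectories are stored in physical units (micrometres, hours) with a
mathematical y-up coordinate convention: x increases rightward along the
anode-to-cathode axis, y increases upward.  Image data arrive in the usual
raster convention (row index increasing downward), so every quantity read
off a mask has its row axis negated before any angle is reported.  This
makes directedness and orientation signs reproducible regardless of how
the microscope happened to be oriented.

Track tables are comma-separated UTF-8 text with a required header and
0-based frame indices: ``cell_id,frame,x,y``.  Coordinates may be in
pixels (converted on read using the optical calibration) or already in
micrometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .errors import InvalidCalibrationError, MaskFormatError, TrackFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "Trajectory",
    "RegionMeasure",
    "effective_pixel_size",
    "read_tracks",
    "write_tracks",
    "measure_labelmask_stack",
    "read_labelmask_stack",
]

#: Minimum pixel count for which a long-axis orientation is reported.
MIN_PIXELS_FOR_AXIS = 3


@dataclass(frozen=True)
class Calibration:
    """Optical calibration of a time-lapse acquisition.

    Attributes
    ----------
    pixel_pitch : float
        Physical sensor pixel size, μm.
    binning : int
        On-camera binning factor (≥ 1).
    objective_mag : float
        Objective magnification (e.g. 10 for a 10× objective).
    intermediate_mag : float
        Intermediate (tube/relay) magnification.
    frame_interval : float
        Time between frames, minutes.
    """

    pixel_pitch: float = 6.5
    binning: int = 2
    objective_mag: float = 10.0
    intermediate_mag: float = 1.5
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        for name in ("pixel_pitch", "binning", "objective_mag",
                     "intermediate_mag", "frame_interval"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidCalibrationError(f"{name} must be positive, got {v!r}")
        if int(self.binning) != self.binning:
            raise InvalidCalibrationError(f"binning must be an integer, got {self.binning!r}")


@dataclass(frozen=True)
class Trajectory:
    """One cell's time-ordered positions in physical units.

    ``times`` are hours and strictly increasing; ``positions`` is an
    (n, 2) array of (x, y) in μm, math y-up convention.
    """

    cell_id: str
    times: np.ndarray
    positions: np.ndarray
    viewfield_id: str = "0"
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a trajectory needs at least 2 time points")
        if p.shape != (t.size, 2):
            raise ValueError("positions must be (n, 2) matching times")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(p)):
            raise ValueError("times and positions must be finite")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def net_displacement(self) -> np.ndarray:
        """First-to-last-frame displacement vector, μm."""
        return self.positions[-1] - self.positions[0]

    @property
    def elapsed_hours(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def path_length(self) -> float:
        """Total path length along the polyline, μm."""
        return float(np.hypot(*np.diff(self.positions, axis=0).T).sum())


@dataclass(frozen=True)
class RegionMeasure:
    """Per-cell, per-frame morphometry extracted from a label mask.

    ``axis_angle`` is the long-axis orientation in radians, axial
    (undirected) on [0, π), measured from +x in the math y-up convention.
    It is ``None`` for degenerate regions (fewer than 3 pixels) and for
    isotropic regions the tie is resolved to 0.0 with ``axis_degenerate``
    set.
    """

    frame_index: int
    label: int
    area: float
    centroid: tuple[float, float]
    n_pixels: int
    axis_angle: float | None
    axis_degenerate: bool = False


def effective_pixel_size(cal: Calibration) -> float:
    """Size of one image pixel at the sample plane, μm/pixel.

    The sensor pitch is multiplied by the binning factor and divided by
    the total optical magnification.  With a 6.5 μm sCMOS pitch, 2×2
    binning, a 10× objective and 1.5× intermediate magnification this
    gives 0.8667 μm/pixel.
    """
    return cal.pixel_pitch * cal.binning / (cal.objective_mag * cal.intermediate_mag)


_REQUIRED_COLUMNS = ("cell_id", "frame", "x", "y")


def read_tracks(
    path: str | Path,
    calibration: Calibration,
    unit_mode: Literal["pixel", "um"] = "pixel",
    viewfield_id: str = "0",
    condition: str = "",
) -> list[Trajectory]:
    """Read a CSV track table into a list of :class:`Trajectory`.

    The table must have header columns ``cell_id, frame, x, y``; frame
    indices are 0-based.  In ``pixel`` mode x/y are multiplied by the
    effective pixel size; in ``um`` mode they are taken as-is.  Times are
    ``frame × frame_interval / 60`` hours.

    Raises
    ------
    TrackFormatError
        On missing columns, duplicate (cell_id, frame) pairs, or
        non-numeric coordinates.
    """
    if unit_mode not in ("pixel", "um"):
        raise TrackFormatError(f"unknown unit_mode {unit_mode!r}")
    try:
        df = pd.read_csv(path, dtype={"cell_id": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrackFormatError(f"cannot parse track table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table {path} missing columns {missing}")
    if df.empty:
        logger.warning("track table %s contains a header but no rows", path)
        return []
    for col in ("frame", "x", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TrackFormatError(f"non-numeric values in column {col!r}") from exc
    if df.duplicated(subset=["cell_id", "frame"]).any():
        dup = df[df.duplicated(subset=["cell_id", "frame"])].iloc[0]
        raise TrackFormatError(
            f"duplicate (cell_id, frame) = ({dup['cell_id']}, {dup['frame']})"
        )
    scale = effective_pixel_size(calibration) if unit_mode == "pixel" else 1.0
    out: list[Trajectory] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        times = grp["frame"].to_numpy(float) * calibration.frame_interval / 60.0
        xy = grp[["x", "y"]].to_numpy(float) * scale
        if len(grp) < 2:
            logger.warning("cell %s has a single frame; skipped", cell_id)
            continue
        out.append(Trajectory(str(cell_id), times, xy,
                              viewfield_id=viewfield_id, condition=condition))
    return out


def write_tracks(
    trajectories: Iterable[Trajectory],
    path: str | Path,
    calibration: Calibration,
    unit_mode: Literal["pixel", "um"] = "um",
) -> None:
    """Write trajectories back to the CSV track-table dialect.

    Inverse of :func:`read_tracks`; round-trips coordinates to full float
    precision. Frame indices are recovered from times via the frame
    interval and rounded to the nearest integer.
    """
    scale = 1.0 / effective_pixel_size(calibration) if unit_mode == "pixel" else 1.0
    rows = []
    for tr in trajectories:
        frames = np.rint(tr.times * 60.0 / calibration.frame_interval).astype(int)
        for f, (x, y) in zip(frames, tr.positions * scale):
            rows.append((tr.cell_id, int(f), x, y))
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def _axis_angle_from_moments(mu: np.ndarray) -> tuple[float, bool]:
    """Long-axis angle in [0, π) from a 2nd-central-moment matrix.

    ``mu`` is the skimage ``moments_central`` array indexed [row_order,
    col_order].  The row axis is negated to convert to math y-up, so the
    covariance terms become var_x = mu[0,2], var_y = mu[2,0],
    cov_xy = −mu[1,1] (all per unit mass).  Returns (angle, degenerate).
    """
    var_x = mu[0, 2]
    var_y = mu[2, 0]
    cov = -mu[1, 1]
    if math.isclose(var_x, var_y, rel_tol=0.0, abs_tol=1e-12 * max(var_x, var_y, 1.0)) \
            and abs(cov) <= 1e-12 * max(var_x, var_y, 1.0):
        return 0.0, True
    ang = 0.5 * math.atan2(2.0 * cov, var_x - var_y)
    return ang % math.pi, False


def measure_labelmask_stack(
    images: Sequence[np.ndarray] | np.ndarray,
    calibration: Calibration,
) -> list[RegionMeasure]:
    """Measure area, centroid and long-axis orientation per label per frame.

    ``images`` is a (T, H, W) stack or a sequence of 2-D integer label
    images with background 0.  Areas are n_pixels × (effective pixel
    size)²; centroids are converted to the math y-up convention with the
    origin at the centre of the top-left pixel (so y = −row × pixel size).
    The axis angle comes from the principal eigenvector of the second
    central moment matrix; regions of fewer than 3 pixels get
    ``axis_angle=None`` and isotropic regions report 0.0 flagged
    degenerate.
    """
    px = effective_pixel_size(calibration)
    out: list[RegionMeasure] = []
    for t, img in enumerate(images):
        img = np.asarray(img)
        if not np.issubdtype(img.dtype, np.integer):
            raise MaskFormatError(f"frame {t}: label mask must be integer, got {img.dtype}")
        if img.ndim != 2:
            raise MaskFormatError(f"frame {t}: label mask must be 2-D")
        for rp in regionprops(img):
            n_pix = int(rp.num_pixels)
            r_c, c_c = rp.centroid
            centroid = (c_c * px, -r_c * px)
            if n_pix < MIN_PIXELS_FOR_AXIS:
                angle, degen = None, True
            else:
                angle, degen = _axis_angle_from_moments(rp.moments_central)
            out.append(RegionMeasure(
                frame_index=t, label=int(rp.label), area=n_pix * px * px,
                centroid=centroid, n_pixels=n_pix,
                axis_angle=angle, axis_degenerate=degen,
            ))
    return out


def read_labelmask_stack(path: str | Path) -> np.ndarray:
    """Load a label-mask stack from a multi-page TIFF or a frame directory.

    A directory is read as its sorted ``*.tif``/``*.tiff``/``*.png``
    members, one frame each.  Returns a (T, H, W) integer array.
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        frames = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not frames:
            raise MaskFormatError(f"no mask frames found in {path}")
        stack = np.stack([iio.imread(p) for p in frames])
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    if not np.issubdtype(stack.dtype, np.integer):
        raise MaskFormatError(f"label stack {path} must be integer-typed")
    return stack
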