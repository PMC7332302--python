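"""Synthetic trajectories and label-mask stacks for electrotaxis analysis.

Real electrotaxis data are time-lapse phase-contrast movies segmented and
tracked upstream; none are bundled here.  This module generates data with
the statistical structure the downstream analysis assumes, so every stage
is testable end to end:

* **Biased persistent random walks.**  At each 10-minute step a cell
  draws a heading from a von Mises distribution whose centre is the
  circular weighted mean of the field direction (weight ``mix_weight``,
  concentration ``kappa_bias``) and the previous heading (weight
  ``1 − mix_weight``, concentration ``kappa_persist``); the two
  contributions are added vectorially, so the effective concentration is
  the magnitude of the summed vector.  Step lengths are independent
  gamma-distributed speeds times dt.  With both concentrations zero the
  walk is isotropic; with ``mix_weight=1`` the headings are i.i.d.
  von Mises and the mean resultant length has the closed form
  I₁(κ)/I₀(κ).

* **Elliptical cell masks.**  Filled ellipses rasterized into integer
  label images, with axial orientations drawn so that the doubled angle
  2θ follows a von Mises distribution about 2×``preferred_axis`` —
  concentration ``kappa_axial`` = 0 gives uniform axes, large values give
  tight alignment (e.g. perpendicular to the field).

All randomness flows from one root seed through per-cell substreams, so
identical configs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .io_tracks import RegionMeasure, Trajectory

__all__ = [
    "WalkConfig",
    "ShapeConfig",
    "simulate_walks",
    "simulate_shape_stack",
    "make_null_pair",
]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the biased persistent random walk.

    Defaults mirror a 6-hour acquisition at 10-minute intervals with net
    speeds of order 10 μm/h.
    """

    n_cells: int = 100
    n_steps: int = 36
    dt: float = 1.0 / 6.0           # hours per step (10 min)
    speed_mean: float = 10.0        # μm/h
    speed_shape: float = 2.0        # gamma shape of per-step speeds
    kappa_bias: float = 0.0         # von Mises concentration toward target
    kappa_persist: float = 0.0      # concentration about previous heading
    target_angle: float = 0.0       # radians; anode→cathode = 0
    mix_weight: float = 0.5         # weight of bias vs persistence
    seed: int = 0
    condition: str = "synthetic"
    viewfield_id: str = "0"

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_steps < 1:
            raise ConfigError("n_cells and n_steps must be >= 1")
        if self.dt <= 0 or self.speed_mean <= 0 or self.speed_shape <= 0:
            raise ConfigError("dt, speed_mean, speed_shape must be > 0")
        if self.kappa_bias < 0 or self.kappa_persist < 0:
            raise ConfigError("concentrations must be >= 0")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ConfigError("mix_weight must be in [0, 1]")


@dataclass(frozen=True)
class ShapeConfig:
    """Parameters of the elliptical-mask generator."""

    n_cells: int = 50
    mean_area: float = 400.0        # μm²
    area_cv: float = 0.2            # coefficient of variation of area
    aspect_mean: float = 3.0        # long/short axis ratio
    kappa_axial: float = 0.0        # concentration of 2θ about 2×preferred_axis
    preferred_axis: float = 0.0     # radians in [0, π)
    image_shape: tuple[int, int] = (512, 512)   # (rows, cols) pixels
    pixel_size: float = 1.0         # μm/pixel
    n_frames: int = 1
    seed: int = 0
    max_retries: int = 200          # placement attempts per cell

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 1:
            raise ConfigError("n_cells and n_frames must be >= 1")
        if self.mean_area <= 0 or self.pixel_size <= 0:
            raise ConfigError("mean_area and pixel_size must be > 0")
        if self.aspect_mean < 1.0:
            raise ConfigError("aspect_mean must be >= 1")
        if self.kappa_axial < 0 or self.area_cv < 0:
            raise ConfigError("kappa_axial and area_cv must be >= 0")


def _draw_headings(rng: np.random.Generator, cfg: WalkConfig) -> np.ndarray:
    """Headings for one cell, shape (n_steps,)."""
    w = cfg.mix_weight
    bias_vec = w * cfg.kappa_bias * np.exp(1j * cfg.target_angle)
    if (1.0 - w) * cfg.kappa_persist == 0.0:
        # no persistence term: headings are i.i.d.; draw in one shot
        kappa_eff = abs(bias_vec)
        if kappa_eff < 1e-12:
            return rng.uniform(-math.pi, math.pi, size=cfg.n_steps)
        return rng.vonmises(np.angle(bias_vec), kappa_eff, size=cfg.n_steps)
    headings = np.empty(cfg.n_steps)
    prev = None
    for t in range(cfg.n_steps):
        z = bias_vec
        if prev is not None:
            z = z + (1.0 - w) * cfg.kappa_persist * np.exp(1j * prev)
        kappa_eff = abs(z)
        if kappa_eff < 1e-12:
            h = rng.uniform(-math.pi, math.pi)
        else:
            h = rng.vonmises(np.angle(z), kappa_eff)
        headings[t] = h
        prev = h
    return headings


def simulate_walks(cfg: WalkConfig) -> list[Trajectory]:
    """Simulate one trajectory per cell from the origin.

    Positions are cumulative sums of step vectors; step t covers
    ``speed_t × dt`` μm along the drawn heading.  Reproducible: the root
    seed is spawned into one independent substream per cell.
    """
    root = np.random.SeedSequence(cfg.seed)
    out: list[Trajectory] = []
    times = np.arange(cfg.n_steps + 1) * cfg.dt
    scale = cfg.speed_mean / cfg.speed_shape
    for i, ss in enumerate(root.spawn(cfg.n_cells)):
        rng = np.random.default_rng(ss)
        headings = _draw_headings(rng, cfg)
        speeds = rng.gamma(cfg.speed_shape, scale, size=cfg.n_steps)
        steps = (speeds * cfg.dt)[:, None] * np.column_stack(
            [np.cos(headings), np.sin(headings)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        out.append(Trajectory(
            cell_id=f"sim{i:05d}", times=times, positions=pos,
            viewfield_id=cfg.viewfield_id, condition=cfg.condition))
    return out


def step_headings(trajectories: Sequence[Trajectory]) -> np.ndarray:
    """All per-step heading angles pooled over trajectories (radians)."""
    hs = []
    for tr in trajectories:
        d = np.diff(tr.positions, axis=0)
        hs.append(np.arctan2(d[:, 1], d[:, 0]))
    return np.concatenate(hs) if hs else np.empty(0)


def _draw_axial_angles(rng: np.random.Generator, cfg: ShapeConfig) -> np.ndarray:
    if cfg.kappa_axial == 0:
        return rng.uniform(0.0, math.pi, size=cfg.n_cells)
    doubled = rng.vonmises(2.0 * cfg.preferred_axis, cfg.kappa_axial,
                           size=cfg.n_cells)
    return np.mod(doubled / 2.0, math.pi)


def _ellipse_pixels(
    shape: tuple[int, int], r0: float, c0: float,
    a_px: float, b_px: float, theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) inside an ellipse.

    ``theta`` is the long-axis angle in math y-up convention; rows map to
    y = −r, so the rotation applied in (row, col) space negates the row
    term.
    """
    h, w = shape
    rad = int(math.ceil(max(a_px, b_px))) + 1
    r_lo, r_hi = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dx = cc - c0
    dy = -(rr - r0)
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return rr[inside], cc[inside]


def simulate_shape_stack(
    cfg: ShapeConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize non-overlapping labelled ellipses with ground truth.

    Returns a (n_frames, H, W) uint16 label stack (shapes static across
    frames) and a ground-truth table with columns label, area (requested,
    μm²), area_px (rasterized), centroid_x, centroid_y (μm, math y-up),
    axis_angle (radians in [0, π)), aspect.

    Raises
    ------
    PlacementError
        If a cell cannot be placed without overlap within the retry
        budget.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    canvas = np.zeros((h, w), dtype=np.uint16)
    angles = _draw_axial_angles(rng, cfg)
    # gamma area distribution: mean = mean_area, cv = area_cv
    if cfg.area_cv > 0:
        shape_k = 1.0 / cfg.area_cv**2
        areas = rng.gamma(shape_k, cfg.mean_area / shape_k, size=cfg.n_cells)
    else:
        areas = np.full(cfg.n_cells, cfg.mean_area)
    rows = []
    for i in range(cfg.n_cells):
        label = i + 1
        area_px2 = areas[i] / cfg.pixel_size**2
        b_px = math.sqrt(area_px2 / (math.pi * cfg.aspect_mean))
        a_px = cfg.aspect_mean * b_px
        margin = a_px + 1.0
        if 2 * margin >= min(h, w):
            raise PlacementError("ellipse does not fit in the image")
        placed = False
        for _ in range(cfg.max_retries):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            rr, cc = _ellipse_pixels((h, w), r0, c0, a_px, b_px, angles[i])
            if canvas[rr, cc].any():
                continue
            canvas[rr, cc] = label
            n_pix = rr.size
            rows.append({
                "label": label,
                "area": areas[i],
                "area_px": n_pix,
                "centroid_x": c0 * cfg.pixel_size,
                "centroid_y": -r0 * cfg.pixel_size,
                "axis_angle": angles[i],
                "aspect": cfg.aspect_mean,
            })
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {label} of {cfg.n_cells} after "
                f"{cfg.max_retries} attempts; reduce density")
    stack = np.broadcast_to(canvas, (cfg.n_frames, h, w)).copy()
    return stack, pd.DataFrame(rows)


def make_null_pair(
    n1: int, n2: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent uniform circular samples (the two-sample null).

    Returns two arrays of angles in (−π, π], reproducible under seed.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("need n1, n2 >= 2")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(-math.pi, math.pi, size=n1 + n2)
    return draws[:n1], draws[n1:]
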