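"""Directional statistics for migration angle data.

Displacement angles, mean resultant (r-) vectors, rose histograms, and
the Mardia–Watson–Wheeler (MWW) two-sample uniform-scores test used to
ask whether the migration tendencies of two cohorts are identical.

Angles are directional radians in (−π, π] measured from the applied
field direction (anode→cathode = 0).  Axial data — undirected cell long
axes on [0, π) — are doubled before any circular operation and the mean
angle halved back, per the standard treatment of axial observations.

The MWW statistic ranks the pooled sample around the circle, maps ranks
to uniform scores β_k = 2π·rank_k/N, and sums the squared resultants of
each group's scores:

    W = 2 Σ_j (C_j² + S_j²) / n_j,   C_j = Σ cos β,  S_j = Σ sin β.

Under the null of identical distributions W is asymptotically χ² with
2 degrees of freedom, so p = exp(−W/2).  A permutation p-value from
random relabellings of the pooled sample is available for small n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, EmptyGroupError, SampleSizeError
from .io_tracks import Trajectory
from .metrics import FieldVector

logger = logging.getLogger(__name__)

__all__ = [
    "AngleSet",
    "MWWResult",
    "displacement_angles",
    "resultant_vector",
    "rose_histogram",
    "mww_test",
]

#: Below this per-group n the asymptotic chi-square p-value is flagged.
ASYMPTOTIC_RELIABLE_N = 10


def _wrap_pi(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


@dataclass(frozen=True)
class AngleSet:
    """A collection of angles, directional or axial.

    Directional angles live in (−π, π]; axial ones in [0, π) and are
    doubled before circular operations.
    """

    angles: np.ndarray
    axial: bool = False

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if a.size and not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        if self.axial:
            a = np.mod(a, np.pi)
        else:
            a = _wrap_pi(a)
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return int(self.angles.size)

    def circular(self) -> np.ndarray:
        """Angles on the full circle: doubled if axial, as-is otherwise."""
        return 2.0 * self.angles if self.axial else self.angles


@dataclass(frozen=True)
class MWWResult:
    W: float
    p_asymptotic: float
    n1: int
    n2: int
    p_permutation: float | None = None
    n_permutations: int = 0
    asymptotic_reliable: bool = True

    def to_dict(self) -> dict:
        return {
            "W": self.W, "p_asymptotic": self.p_asymptotic,
            "p_permutation": self.p_permutation,
            "n1": self.n1, "n2": self.n2,
            "n_permutations": self.n_permutations,
            "asymptotic_reliable": self.asymptotic_reliable,
        }


def displacement_angles(
    trajectories: Sequence[Trajectory], field: FieldVector
) -> AngleSet:
    """Net-displacement angles relative to the field direction.

    Computed with the two-argument arctangent after rotating the field
    direction onto +x; zero-displacement cells are excluded and counted.
    """
    disp = np.array([tr.net_displacement for tr in trajectories], dtype=float)
    if disp.size == 0:
        logger.warning("no trajectories given; empty angle set")
        return AngleSet(np.empty(0))
    norms = np.hypot(disp[:, 0], disp[:, 1])
    moving = norms > 0
    if not moving.any():
        logger.warning("all %d net displacements are zero; empty angle set",
                       len(trajectories))
        return AngleSet(np.empty(0))
    if (~moving).any():
        logger.warning("%d zero-displacement cell(s) excluded from angles",
                       int((~moving).sum()))
    ang = np.arctan2(disp[moving, 1], disp[moving, 0]) - field.angle
    return AngleSet(_wrap_pi(ang))


def resultant_vector(a: AngleSet) -> tuple[float, float | None]:
    """Mean resultant vector (r, mean_angle) of an angle set.

    r ∈ [0, 1] measures concentration; mean_angle is None when r = 0
    (no preferred direction).  Axial sets are doubled internally and the
    mean angle halved back onto [0, π).
    """
    if a.n < 1:
        raise EmptyGroupError("resultant vector of an empty angle set")
    z = np.exp(1j * a.circular()).mean()
    r = float(abs(z))
    if r < 1e-12:
        return 0.0, None
    mean = float(np.angle(z))
    if a.axial:
        mean = (mean / 2.0) % math.pi
    return r, mean


def rose_histogram(
    a: AngleSet, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram of angles in equal bins around the circle.

    The first bin is centred on 0 rad (the field direction); bins are
    half-open [lo, hi).  Returns (edges, counts) with len(edges) =
    n_bins + 1 and counts summing to n.
    """
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 2:
        raise ConfigError(f"n_bins must be an integer >= 2, got {n_bins!r}")
    width = 2.0 * np.pi / n_bins
    edges = -width / 2.0 + width * np.arange(n_bins + 1)
    shifted = np.mod(a.angles + width / 2.0, 2.0 * np.pi)
    idx = np.minimum((shifted / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def plot_rose(a: AngleSet, n_bins: int = 12, ax=None, **bar_kwargs):
    """Rose (angle histogram) plot with the mean resultant vector arrow.

    Frequencies per bin on a polar axis, 0 rad = field direction at the
    right; the r-vector is drawn scaled to the outer ring.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    edges, counts = rose_histogram(a, n_bins)
    width = 2.0 * np.pi / n_bins
    centres = (edges[:-1] + edges[1:]) / 2.0
    bar_kwargs.setdefault("alpha", 0.7)
    bar_kwargs.setdefault("edgecolor", "black")
    ax.bar(centres, counts, width=width, align="center", **bar_kwargs)
    if a.n:
        r, mean = resultant_vector(a)
        if mean is not None:
            ax.annotate("", xy=(mean, r * counts.max()), xytext=(0.0, 0.0),
                        arrowprops=dict(arrowstyle="->", lw=2))
    return ax


def _mww_statistic(scores: np.ndarray, n1: int) -> float:
    c, s = np.cos(scores), np.sin(scores)
    c1, s1 = c[:n1].sum(), s[:n1].sum()
    c2, s2 = c[n1:].sum(), s[n1:].sum()
    n2 = scores.size - n1
    return 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / n2)


def mww_test(
    a: AngleSet,
    b: AngleSet,
    n_permutations: int = 0,
    seed: int | None = None,
) -> MWWResult:
    """Mardia–Watson–Wheeler two-sample uniform-scores test.

    Tests the null that both angle sets come from the same circular
    distribution.  Ties in the pooled sample are broken by infinitesimal
    random jitter under ``seed`` (also used for the permutation draws).
    With ``n_permutations`` > 0 a permutation p-value (b+1)/(B+1) from
    random relabellings is reported alongside the asymptotic one.
    """
    if a.n < 2 or b.n < 2:
        raise SampleSizeError(f"need n >= 2 per group, got {a.n} and {b.n}")
    if a.axial != b.axial:
        raise ConfigError("cannot mix axial and directional angle sets")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a.circular(), b.circular()])
    n1, n = a.n, pooled.size
    # circular ranks: order around the circle; ties jittered reproducibly
    if np.unique(pooled).size < n:
        pooled = pooled + rng.uniform(-1e-9, 1e-9, size=n)
    ranks = np.empty(n, dtype=float)
    ranks[np.argsort(pooled, kind="stable")] = np.arange(1, n + 1)
    scores = 2.0 * np.pi * ranks / n
    W = _mww_statistic(scores, n1)
    p_asym = float(stats.chi2.sf(W, df=2))
    reliable = min(a.n, b.n) >= ASYMPTOTIC_RELIABLE_N
    if not reliable:
        logger.warning("min group size %d < %d: asymptotic p unreliable; "
                       "prefer the permutation p-value",
                       min(a.n, b.n), ASYMPTOTIC_RELIABLE_N)
    p_perm = None
    if n_permutations > 0:
        # vectorised random relabellings: each row of `order` is a
        # permutation; the first n1 entries form the relabelled group A
        keys = rng.random((n_permutations, n))
        order = np.argsort(keys, axis=1)
        cs = np.cos(scores)[order[:, :n1]].sum(axis=1)
        ss = np.sin(scores)[order[:, :n1]].sum(axis=1)
        # group B resultants follow from totals (Σcosβ, Σsinβ over all scores)
        ct, st = np.cos(scores).sum(), np.sin(scores).sum()
        n2 = n - n1
        W_perm = 2.0 * ((cs**2 + ss**2) / n1 + ((ct - cs)**2 + (st - ss)**2) / n2)
        exceed = int((W_perm >= W - 1e-12).sum())
        p_perm = (exceed + 1) / (n_permutations + 1)
    return MWWResult(W=float(W), p_asymptotic=p_asym, n1=a.n, n2=b.n,
                     p_permutation=p_perm, n_permutations=n_permutations,
                     asymptotic_reliable=reliable)
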