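"""Experiment orchestration: filters, summaries, and group comparisons.

An experiment is a set of labelled conditions (one track table or
simulation spec each, plus the applied field).  The pipeline applies the
study's filtering rules, computes the migration metrics per condition,
runs the circular two-sample comparisons, and writes CSV/JSON reports:

* only cells tracked through every frame of their viewfield are kept
  (incomplete tracks are excluded and logged);
* each condition should contain at least ``min_cells`` cells (default
  100); smaller cohorts are flagged, not dropped;
* group values are reported as mean ± 1.96 × SEM, the normal-theory 95%
  confidence interval.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import circular, metrics, synthetic
from .errors import ConfigError, SampleSizeError
from .io_tracks import Calibration, Trajectory, read_tracks, write_tracks
from .metrics import FieldVector

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionSpec",
    "ExperimentConfig",
    "GroupSummary",
    "filter_complete_tracks",
    "ci95",
    "compare_groups",
    "anova_oneway",
    "run_experiment",
    "load_config",
]

DEFAULT_MIN_CELLS = 100
DEFAULT_CI_MULTIPLIER = 1.96


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: where its tracks come from and its field."""

    label: str
    field: FieldVector
    tracks: str | None = None               # CSV track table path
    unit_mode: str = "um"
    simulate: Mapping[str, Any] | None = None   # WalkConfig overrides

    def __post_init__(self) -> None:
        if (self.tracks is None) == (self.simulate is None):
            raise ConfigError(
                f"condition {self.label!r}: give exactly one of tracks/simulate")


@dataclass(frozen=True)
class ExperimentConfig:
    conditions: tuple[ConditionSpec, ...]
    calibration: Calibration = dc_field(default_factory=Calibration)
    min_cells: int = DEFAULT_MIN_CELLS
    require_complete: bool = True
    ci_multiplier: float = DEFAULT_CI_MULTIPLIER
    mww_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        if self.min_cells < 1:
            raise ConfigError("min_cells must be >= 1")


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition summary statistics (mean ± CI half-widths)."""

    label: str
    n_cells: int
    directedness: float
    directedness_ci: float
    speed: float
    speed_ci: float
    r_length: float
    r_angle: float | None
    orientation: float | None = None
    orientation_ci: float | None = None
    low_n: bool = False

    def to_row(self) -> dict:
        return {
            "label": self.label, "n_cells": self.n_cells,
            "directedness": self.directedness,
            "directedness_ci95": self.directedness_ci,
            "speed_um_per_h": self.speed, "speed_ci95": self.speed_ci,
            "r_length": self.r_length,
            "r_angle_rad": np.nan if self.r_angle is None else self.r_angle,
            "orientation": np.nan if self.orientation is None else self.orientation,
            "orientation_ci95": (np.nan if self.orientation_ci is None
                                 else self.orientation_ci),
            "low_n_flag": self.low_n,
        }


def filter_complete_tracks(
    trajectories: Sequence[Trajectory],
    frame_range: tuple[int, int] | None = None,
    frame_interval_minutes: float = 10.0,
) -> tuple[list[Trajectory], list[str]]:
    """Keep only cells tracked through every frame of their viewfield.

    The frame grid is inferred per viewfield as [min, max] of observed
    frame indices unless ``frame_range`` overrides it.  Returns the
    retained trajectories and the excluded cell ids.
    """
    trajectories = list(trajectories)
    if not trajectories:
        return [], []
    dt_h = frame_interval_minutes / 60.0
    frames = {tr.cell_id: np.rint(tr.times / dt_h).astype(int)
              for tr in trajectories}
    by_vf: dict[str, tuple[int, int]] = {}
    if frame_range is None:
        for tr in trajectories:
            f = frames[tr.cell_id]
            lo, hi = int(f.min()), int(f.max())
            cur = by_vf.get(tr.viewfield_id)
            by_vf[tr.viewfield_id] = (
                (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi)))
    kept, excluded = [], []
    for tr in trajectories:
        lo, hi = frame_range if frame_range is not None else by_vf[tr.viewfield_id]
        need = set(range(lo, hi + 1))
        if need.issubset(set(frames[tr.cell_id].tolist())):
            kept.append(tr)
        else:
            excluded.append(tr.cell_id)
    if excluded:
        logger.info("completeness filter removed %d/%d track(s)",
                    len(excluded), len(trajectories))
    return kept, excluded


def ci95(
    values: Sequence[float], multiplier: float = DEFAULT_CI_MULTIPLIER
) -> tuple[float, float]:
    """Mean and CI half-width ``multiplier × SD/√n`` (sample SD, n−1).

    The multiplier 1.96 gives the normal-approximation 95% interval on
    the mean regardless of n.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SampleSizeError("confidence interval needs n >= 2")
    sem = v.std(ddof=1) / np.sqrt(v.size)
    return float(v.mean()), float(multiplier * sem)


def compare_groups(
    a: Sequence[float], b: Sequence[float]
) -> dict[str, float]:
    """Two-tailed Welch t-test between two scalar metric groups.

    Degenerate (zero-variance) identical groups short-circuit to
    t = 0, p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("need n >= 2 per group")
    if a.std() == 0 and b.std() == 0:
        same = float(a.mean() == b.mean())
        return {"t": 0.0 if same else np.inf, "p": 1.0 if same else 0.0,
                "n1": a.size, "n2": b.size}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "n1": int(a.size), "n2": int(b.size)}


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across ≥3 groups with Tukey HSD post-hoc.

    Delegates to scipy (F test) and statsmodels (Tukey).  Returns the F
    statistic, p-value, degrees of freedom (k−1, N−k) and the Tukey
    pairwise table as records.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(groups)
    arrays = [np.asarray(groups[k], float) for k in labels]
    if len(arrays) < 3:
        raise ConfigError("one-way ANOVA here is for 3+ groups; use compare_groups")
    f, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes)
    tukey = [dict(zip(tk.summary().data[0], row)) for row in tk.summary().data[1:]]
    return {"F": float(f), "p": float(p),
            "df_between": len(arrays) - 1, "df_within": n_total - len(arrays),
            "tukey": tukey}


def _load_condition(
    spec: ConditionSpec, cfg: ExperimentConfig
) -> list[Trajectory]:
    if spec.tracks is not None:
        path = Path(spec.tracks)
        if not path.exists():
            raise ConfigError(f"condition {spec.label!r}: missing source {path}")
        return read_tracks(path, cfg.calibration, unit_mode=spec.unit_mode,
                           condition=spec.label)
    walk_kwargs = dict(spec.simulate or {})
    walk_kwargs.setdefault("seed", cfg.seed)
    walk_kwargs.setdefault("condition", spec.label)
    return synthetic.simulate_walks(synthetic.WalkConfig(**walk_kwargs))


def _summarize(
    label: str,
    trajs: Sequence[Trajectory],
    fv: FieldVector,
    cfg: ExperimentConfig,
) -> tuple[GroupSummary, circular.AngleSet, pd.DataFrame]:
    dire = metrics.directedness(trajs, fv)
    speeds = np.array([metrics.speed(tr) for tr in trajs])
    d_mean, d_ci = ci95(dire.per_cell, cfg.ci_multiplier)
    s_mean, s_ci = ci95(speeds, cfg.ci_multiplier)
    angles = circular.displacement_angles(trajs, fv)
    r, mean_ang = circular.resultant_vector(angles)
    summary = GroupSummary(
        label=label, n_cells=len(trajs),
        directedness=d_mean, directedness_ci=d_ci,
        speed=s_mean, speed_ci=s_ci,
        r_length=r, r_angle=mean_ang,
        low_n=len(trajs) < cfg.min_cells,
    )
    if summary.low_n:
        logger.warning("condition %r has %d cells (< %d)",
                       label, len(trajs), cfg.min_cells)
    per_cell = metrics.metrics_table(trajs, fv)
    return summary, angles, per_cell


def run_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> dict:
    """Run the full analysis for every condition and all pairwise tests.

    Deterministic given config + seed.  When ``out_dir`` is given, writes
    ``summary.csv``, ``percell_<label>.csv``, ``rose_<label>.csv``,
    ``comparisons.json`` and a provenance block (config hash, seed,
    package version).
    """
    from . import __version__

    summaries: list[GroupSummary] = []
    angle_sets: dict[str, circular.AngleSet] = {}
    per_cell: dict[str, pd.DataFrame] = {}
    for spec in cfg.conditions:
        trajs = _load_condition(spec, cfg)
        if cfg.require_complete:
            trajs, dropped = filter_complete_tracks(
                trajs, frame_interval_minutes=cfg.calibration.frame_interval)
        summ, angles, table = _summarize(spec.label, trajs, spec.field, cfg)
        summaries.append(summ)
        angle_sets[spec.label] = angles
        per_cell[spec.label] = table
    comparisons = []
    labels = [c.label for c in cfg.conditions]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            mww = circular.mww_test(
                angle_sets[la], angle_sets[lb],
                n_permutations=cfg.mww_permutations, seed=cfg.seed)
            t_dir = compare_groups(per_cell[la]["cos_phi"].dropna(),
                                   per_cell[lb]["cos_phi"].dropna())
            t_spd = compare_groups(per_cell[la]["speed"], per_cell[lb]["speed"])
            comparisons.append({
                "a": la, "b": lb, "mww": mww.to_dict(),
                "directedness_t": t_dir, "speed_t": t_spd,
            })
    summary_df = pd.DataFrame([s.to_row() for s in summaries])
    cfg_hash = hashlib.sha256(
        repr(cfg).encode()).hexdigest()[:16]
    report = {
        "summary": summary_df,
        "comparisons": comparisons,
        "angles": angle_sets,
        "per_cell": per_cell,
        "provenance": {"config_sha256": cfg_hash, "seed": cfg.seed,
                       "version": __version__},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        for lab in labels:
            per_cell[lab].to_csv(out / f"percell_{lab}.csv", index=False,
                                 float_format="%.10g")
            edges, counts = circular.rose_histogram(angle_sets[lab], 12)
            pd.DataFrame({"bin_lo_rad": edges[:-1], "bin_hi_rad": edges[1:],
                          "count": counts}).to_csv(
                out / f"rose_{lab}.csv", index=False, float_format="%.10g")
        with open(out / "comparisons.json", "w") as fh:
            json.dump({"comparisons": comparisons,
                       "provenance": report["provenance"]}, fh, indent=2)
    return report


def _field_from_dict(d: Mapping[str, Any]) -> FieldVector:
    return FieldVector(
        direction=tuple(d.get("direction", (1.0, 0.0))),
        strength=float(d.get("strength", 0.0)),
        on_time=float(d.get("on_time", 0.0)),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file.

    Layout::

        seed: 7
        min_cells: 100
        calibration: {pixel_pitch: 6.5, binning: 2, objective_mag: 10,
                      intermediate_mag: 1.5, frame_interval: 10}
        conditions:
          - label: control
            field: {direction: [1, 0], strength: 0}
            tracks: control.csv
          - label: stimulated
            field: {direction: [1, 0], strength: 300}
            simulate: {kappa_bias: 5.0, mix_weight: 1.0, n_cells: 200}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "conditions" not in raw:
        raise ConfigError(f"{path}: expected a mapping with a 'conditions' list")
    conds = []
    for c in raw["conditions"]:
        conds.append(ConditionSpec(
            label=str(c["label"]),
            field=_field_from_dict(c.get("field", {})),
            tracks=c.get("tracks"),
            unit_mode=c.get("unit_mode", "um"),
            simulate=c.get("simulate"),
        ))
    cal = Calibration(**raw.get("calibration", {}))
    return ExperimentConfig(
        conditions=tuple(conds),
        calibration=cal,
        min_cells=int(raw.get("min_cells", DEFAULT_MIN_CELLS)),
        require_complete=bool(raw.get("require_complete", True)),
        ci_multiplier=float(raw.get("ci_multiplier", DEFAULT_CI_MULTIPLIER)),
        mww_permutations=int(raw.get("mww_permutations", 10_000)),
        seed=int(raw.get("seed", 0)),
    )
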