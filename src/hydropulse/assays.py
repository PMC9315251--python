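"""Plate-reader assay normalizations for the loaded-cell readouts.

The biology side of the platform quantifies viability (CCK-8), membrane
damage (LDH), oxidative and nitrosative stress (ROS, NO) and cytokine
release (TNF-alpha) after a pressure shot.  This module implements the
background-corrected, per-10k-cell normalizations those readouts use, the
CCK-8 standard-curve cell counting, a synthetic plate generator for
testing, and tidy per-group summary tables ready for any standard
group-comparison routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "survival_rate",
    "ldh_release",
    "relative_ros",
    "StandardCurve",
    "cells_from_od",
    "synth_plate",
    "summarize_plate",
]

PLATE_COLUMNS = ["group", "time_h", "replicate", "assay", "value", "blank"]


def survival_rate(od_experiment: float, od_control: float, od_background: float) -> float:
    """Cell survival as percent of control.

    100 * (OD_exp - OD_bg) / (OD_ctrl - OD_bg).  Background-subtracts
    both wells; requires the control well to sit above background.
    """
    if od_control <= od_background:
        raise ValueError("invalid control: od_control must exceed od_background")
    return 100.0 * (od_experiment - od_background) / (od_control - od_background)


def _per_cell_ratio(num_val, num_blank, num_cells, den_val, den_blank, den_cells) -> float:
    if num_cells <= 0 or den_cells <= 0:
        raise ValueError("cell counts must be positive")
    denominator = (den_val - den_blank) / den_cells
    if denominator <= 0:
        raise ValueError("control signal must exceed its blank")
    return ((num_val - num_blank) / num_cells) / denominator


def ldh_release(
    od_experiment: float,
    od_blank_experiment: float,
    n_cells_experiment: float,
    od_control: float,
    od_blank_control: float,
    n_cells_control: float,
) -> float:
    """Accumulated LDH release per 10k cells, as a ratio to control.

    Each group's blank-corrected OD is divided by its own cell count
    before taking the ratio, so unequal well densities cancel.  Counts may
    be given in cells or in 10k-cell units; the ratio is invariant as long
    as both use the same unit.
    """
    return _per_cell_ratio(
        od_experiment, od_blank_experiment, n_cells_experiment, od_control, od_blank_control, n_cells_control
    )


def relative_ros(
    value_experiment: float,
    value_blank: float,
    n_cells_experiment: float,
    value_control: float,
    value_blank_control: float,
    n_cells_control: float,
) -> float:
    """Per-cell fluorescence fold-change over control (ROS/NO normalization)."""
    return _per_cell_ratio(
        value_experiment, value_blank, n_cells_experiment, value_control, value_blank_control, n_cells_control
    )


@dataclass(frozen=True)
class StandardCurve:
    """Linear CCK-8 standard curve: cells = slope * OD + intercept.

    slope is cells per OD unit; fit_range is the OD interval the curve
    was established on — queries outside it warn, since plate readers
    saturate.
    """

    slope: float
    intercept: float
    fit_range: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if self.fit_range[0] >= self.fit_range[1]:
            raise ValueError("fit_range must be an increasing interval")


def cells_from_od(od: float, curve: StandardCurve) -> float:
    """Cell count from an OD reading via the standard curve, floored at 0."""
    lo, hi = curve.fit_range
    if not lo <= od <= hi:
        warnings.warn(f"OD {od} outside the standard-curve fit range [{lo}, {hi}]", stacklevel=2)
    return max(curve.slope * od + curve.intercept, 0.0)


def synth_plate(
    design: dict[tuple[str, float], float] | pd.DataFrame,
    *,
    assay: str = "ROS",
    control_group: str = "control",
    n_replicates: int = 4,
    cv: float = 0.05,
    blank: float = 0.05,
    control_mean: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic plate table with programmed group effects.

    `design` maps (group, time_h) to the fold-effect over control; the
    blank-corrected control signal is `control_mean`.  Replicate values
    get multiplicative lognormal noise of coefficient of variation `cv`,
    mimicking pipetting/reader scatter.  The control group at each time
    point is generated too.  Reproducible under a fixed seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(design, pd.DataFrame):
        design = {(r.group, float(r.time_h)): float(r.effect) for r in design.itertuples()}
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))  # lognormal sigma for the requested CV
    mu = -0.5 * sigma**2  # unit mean

    times = sorted({t for (_, t) in design})
    rows = []
    for t in times:
        groups = [(control_group, 1.0)] + [(g, e) for (g, tt), e in design.items() if tt == t]
        for group, effect in groups:
            noise = np.exp(mu + sigma * rng.standard_normal(n_replicates)) if cv > 0 else np.ones(n_replicates)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "group": group,
                        "time_h": t,
                        "replicate": rep,
                        "assay": assay,
                        "value": blank + control_mean * effect * noise[rep - 1],
                        "blank": blank,
                    }
                )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def summarize_plate(
    plate: pd.DataFrame,
    *,
    control_group: str = "control",
    cell_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-group normalized table.

    For CCK8 rows the statistic is survival (% control); for every other
    assay it is the per-cell fold-change over the same-time control.
    `cell_counts` (columns group, time_h, n_cells) supplies per-well
    densities; equal counts are assumed when omitted.  Output columns:
    group, time_h, assay, n, mean, sem, statistic.
    """
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    def _count(group: str, time_h: float) -> float:
        if cell_counts is None:
            return 1.0
        sel = cell_counts[(cell_counts["group"] == group) & (cell_counts["time_h"] == time_h)]
        return float(sel["n_cells"].iloc[0]) if len(sel) else 1.0

    out = []
    for (assay, time_h), sub in plate.groupby(["assay", "time_h"]):
        ctrl = sub[sub["group"] == control_group]
        if ctrl.empty:
            raise ValueError(f"no control group rows for assay={assay!r}, time_h={time_h}")
        ctrl_corr = (ctrl["value"] - ctrl["blank"]).mean()
        ctrl_blank = ctrl["blank"].mean()
        n_ctrl = _count(control_group, time_h)
        for group, g in sub.groupby("group"):
            if assay == "CCK8":
                vals = [
                    survival_rate(v, ctrl_corr + ctrl_blank, b) for v, b in zip(g["value"], g["blank"])
                ]
                stat = "survival_percent"
            else:
                vals = [
                    relative_ros(v, b, _count(group, time_h), ctrl_corr + ctrl_blank, ctrl_blank, n_ctrl)
                    for v, b in zip(g["value"], g["blank"])
                ]
                stat = "fold_of_control"
            vals = np.asarray(vals, dtype=float)
            out.append(
                {
                    "group": group,
                    "time_h": time_h,
                    "assay": assay,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                    "statistic": stat,
                }
            )
    return pd.DataFrame(out).sort_values(["assay", "time_h", "group"]).reset_index(drop=True)
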