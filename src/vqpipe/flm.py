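"""Fluorescence-labelled microsphere (FLM) cube processing.

15 um microspheres injected intravenously lodge in pulmonary capillaries in
proportion to regional blood flow; the dried lung is cut into 12 mm cubes
whose fluorescence, normalized by cube weight, measures flow per unit
tissue mass.  Because the postmortem cubes lose anatomic registration, cubes
are assigned to analysis ROIs by their center coordinate, and regional flow
is the ratio of summed fluorescence to summed weight per ROI, renormalized
across ROIs — the same intensive flow-per-mass quantity the DECT branch
reports.  (On this synthetic phantom cubes and images share one coordinate
frame; in vivo that mapping is itself a source of error.)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .perfusion import ROI_CODES, ROI_NAMES, ROISet, RegionalPerfusion

__all__ = ["normalize_fluorescence", "cubes_to_rois", "regional_flm"]

REQUIRED_COLUMNS = ("cube_x_mm", "cube_y_mm", "cube_z_mm", "weight_mg", "color", "fluorescence_au", "is_lung")


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"microsphere table is missing columns {missing}")


def normalize_fluorescence(table: pd.DataFrame, color: str) -> pd.Series:
    """Weight-normalized per-cube perfusion values for one color, summing to 1.

    value_i = fluorescence_i / weight_i over lung cubes, then divided by the
    total.  Cubes with non-positive weight are rejected with a warning.
    """
    _validate(table)
    sub = table[(table["color"] == color) & table["is_lung"]]
    if sub.empty:
        raise ValueError(f"color {color!r} not present among lung cubes")
    bad = sub["weight_mg"] <= 0
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} cube(s) with non-positive weight")
        sub = sub[~bad]
    values = sub["fluorescence_au"] / sub["weight_mg"]
    total = values.sum()
    if total <= 0:
        raise ValueError("all fluorescence values are zero; cannot normalize")
    return values / total


def cubes_to_rois(table: pd.DataFrame, rois: ROISet) -> pd.DataFrame:
    """Assign each cube the ROI label at its center coordinate.

    Cubes whose center falls outside every ROI (or outside the image) are
    flagged ``unassigned``.
    """
    _validate(table)
    centers = table[["cube_x_mm", "cube_y_mm", "cube_z_mm"]].to_numpy(dtype=float)
    idx = np.floor(rois.grid.world_to_index(centers)).astype(int)
    labels = np.full(len(table), "unassigned", dtype=object)
    inside = np.all(idx >= 0, axis=1) & np.all(idx < np.asarray(rois.grid.shape), axis=1)
    codes = np.zeros(len(table), dtype=int)
    codes[inside] = rois.labels[tuple(idx[inside].T)]
    for code, name in ROI_NAMES.items():
        labels[codes == code] = name
    out = table.copy()
    out["roi"] = labels
    return out


def regional_flm(
    labeled: pd.DataFrame,
    color: str | None = None,
    timepoint: int | None = None,
    aggregate: str = "flow_per_mass",
) -> RegionalPerfusion:
    """Regional blood-flow fractions from an ROI-labeled cube table.

    ``flow_per_mass`` (default): per ROI, summed fluorescence over summed
    weight, renormalized — flow per unit tissue mass, directly comparable to
    the mass-normalized DECT regional values.  ``sum_normalized``: per-ROI
    sum of the weight-normalized per-cube values, renormalized.
    """
    if "roi" not in labeled.columns:
        raise ValueError("table has no 'roi' column; run cubes_to_rois first")
    if aggregate not in ("flow_per_mass", "sum_normalized"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    sub = labeled[labeled["is_lung"]]
    if color is not None:
        sub = sub[sub["color"] == color]
    if sub.empty:
        raise ValueError("no lung cubes to aggregate")
    sub = sub[sub["weight_mg"] > 0]

    vals = []
    if aggregate == "sum_normalized":
        per_cube = sub["fluorescence_au"] / sub["weight_mg"]
        per_cube = per_cube / per_cube.sum()
        for code in ROI_CODES:
            vals.append(float(per_cube[sub["roi"] == ROI_NAMES[code]].sum()))
    else:
        for code in ROI_CODES:
            roi = sub[sub["roi"] == ROI_NAMES[code]]
            if roi.empty or roi["weight_mg"].sum() <= 0:
                raise ValueError(f"ROI {ROI_NAMES[code]} has no usable cubes")
            vals.append(float(roi["fluorescence_au"].sum() / roi["weight_mg"].sum()))
    vals = np.asarray(vals)
    if vals.sum() <= 0:
        raise ValueError("all regional values are zero")
    return RegionalPerfusion(values=vals / vals.sum(), method="FLM", timepoint=timepoint)
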