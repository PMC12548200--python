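"""Normalized perfused-blood-volume maps, analysis ROIs and V/Q summaries.

The iodine enhancement image is proportional to the perfused blood volume of
each voxel under the constant-blood-iodine assumption; normalizing by the
sum over the entire lung parenchyma (vessels excluded) turns it into a map
of regional perfusion fractions, so the sum over any region of interest is
that region's share of the overall perfused blood volume.  Regional values
are divided by the VNC-derived tissue mass of the ROI and renormalized, so
the compared quantity is perfusion per unit tissue mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dect import DecompositionResult
from .grid import Grid, require_same_grid
from .ventilation import VentilationMap

__all__ = [
    "VESSEL_THRESHOLD_HU",
    "ROI_RIGHT",
    "ROI_LEFT_CRANIAL",
    "ROI_LEFT_CAUDAL",
    "ROI_NAMES",
    "PerfusionMap",
    "ROISet",
    "RegionalPerfusion",
    "segment_vessels",
    "tissue_mass",
    "perfusion_map",
    "split_rois",
    "regional_perfusion",
    "accumulation_table",
    "vq_profiles",
    "vq_classify",
]

# iodine-image threshold (HU) for vessel region growing; blood-pool
# enhancement sits well above parenchymal enhancement plus noise
VESSEL_THRESHOLD_HU = 150.0

ROI_RIGHT = 1
ROI_LEFT_CRANIAL = 2
ROI_LEFT_CAUDAL = 3
ROI_NAMES = {ROI_RIGHT: "right", ROI_LEFT_CRANIAL: "left_cranial", ROI_LEFT_CAUDAL: "left_caudal"}
ROI_CODES = (ROI_RIGHT, ROI_LEFT_CRANIAL, ROI_LEFT_CAUDAL)


@dataclass
class PerfusionMap:
    """Voxelwise perfusion fractions summing to 1 over the parenchyma."""

    pp: np.ndarray
    parenchyma: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        if not np.all(self.pp >= 0):
            raise ValueError("perfusion fractions must be non-negative")


@dataclass
class ROISet:
    """Right / left-cranial / left-caudal analysis regions."""

    labels: np.ndarray
    grid: Grid
    split_slice: int
    axis: int = 2

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class RegionalPerfusion:
    """Per-ROI perfusion fractions (right, left_cranial, left_caudal), sum 1."""

    values: np.ndarray
    method: str
    timepoint: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3,):
            raise ValueError("expected exactly 3 ROI values")
        if np.any(self.values < 0) or not np.isclose(self.values.sum(), 1.0, atol=1e-9):
            raise ValueError("regional perfusion must be non-negative and sum to 1")


def segment_vessels(
    volume: np.ndarray,
    grid: Grid,
    seed_points_mm: np.ndarray,
    threshold_hu: float,
) -> np.ndarray:
    """Threshold region growing (26-connected) from world-coordinate seeds."""
    volume = np.asarray(volume, dtype=float)
    seeds = np.atleast_2d(np.asarray(seed_points_mm, dtype=float))
    idx = np.rint(grid.world_to_index(seeds)).astype(int)
    for pt in idx:
        if np.any(pt < 0) or np.any(pt >= np.asarray(grid.shape)):
            raise ValueError(f"seed point {pt} lies outside the volume")
    above = volume >= threshold_hu
    labeled, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    comp_ids = set()
    for pt in idx:
        cid = labeled[tuple(pt)]
        if cid == 0:
            raise ValueError(f"seed at index {tuple(pt)} is below threshold; no growth")
        comp_ids.add(int(cid))
    return np.isin(labeled, sorted(comp_ids))


def tissue_mass(vnc: np.ndarray, voxel_volume_ml: float) -> np.ndarray:
    """Tissue mass (g) per voxel from the VNC image.

    Water-equivalent CT density rho = 1 + HU/1000 g/ml, clipped to [0, 1.1].
    """
    rho = np.clip(1.0 + np.asarray(vnc, dtype=float) / 1000.0, 0.0, 1.1)
    return rho * float(voxel_volume_ml)


def perfusion_map(
    iodine: np.ndarray,
    grid: Grid,
    parenchyma: np.ndarray,
    vessels: np.ndarray | None = None,
    clip_negative: bool = True,
) -> PerfusionMap:
    """Sum-normalize the iodine image over the parenchyma (vessels excluded)."""
    parenchyma = np.asarray(parenchyma).astype(bool)
    if vessels is not None:
        parenchyma = parenchyma & ~np.asarray(vessels).astype(bool)
    vals = np.asarray(iodine, dtype=float)
    if clip_negative:
        vals = np.maximum(vals, 0.0)
    pp = np.where(parenchyma, vals, 0.0)
    total = pp.sum()
    if total <= 0:
        raise ValueError("iodine image is zero over the parenchyma; cannot normalize")
    return PerfusionMap(pp=pp / total, parenchyma=parenchyma, grid=grid)


def split_rois(
    left: np.ndarray,
    right: np.ndarray,
    grid: Grid,
    axis: int = 2,
) -> ROISet:
    """Build the three ROIs; the left lung is split axially into equal volumes.

    Slices are scanned from the cranial end (descending index along
    ``axis``); the first slice at which the cumulative left-lung voxel count
    reaches half the total closes the cranial ROI, with the tie slice
    assigned caudal.
    """
    left = np.asarray(left).astype(bool)
    right = np.asarray(right).astype(bool)
    if not left.any():
        raise ValueError("left mask is empty")
    sum_axes = tuple(a for a in range(3) if a != axis)
    counts = left.sum(axis=sum_axes)
    total = counts.sum()
    order = np.arange(grid.shape[axis])[::-1]  # cranial = high index first
    cum = np.cumsum(counts[order])
    # boundary: first slice whose cumulative count strictly exceeds half;
    # a slice landing exactly on half stays cranial, the crossing slice is caudal
    boundary_pos = int(np.argmax(cum > total / 2.0))
    split_slice = int(order[boundary_pos])  # first caudal slice

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[right] = ROI_RIGHT
    sl = [slice(None)] * 3
    sl[axis] = slice(split_slice + 1, None)
    cranial = np.zeros(grid.shape, dtype=bool)
    cranial[tuple(sl)] = True
    labels[left & cranial] = ROI_LEFT_CRANIAL
    labels[left & ~cranial] = ROI_LEFT_CAUDAL
    return ROISet(labels=labels, grid=grid, split_slice=split_slice, axis=axis)


def regional_perfusion(
    pp: PerfusionMap,
    mass: np.ndarray,
    rois: ROISet,
    method: str = "DECT",
    timepoint: int | None = None,
) -> RegionalPerfusion:
    """Per-ROI (sum pp) / (sum mass), renormalized across the three ROIs."""
    require_same_grid(pp.grid, rois.grid)
    vals = []
    for code in ROI_CODES:
        m = rois.mask(code) & pp.parenchyma
        roi_mass = float(np.asarray(mass)[m].sum())
        if roi_mass <= 0:
            raise ValueError(f"ROI {ROI_NAMES[code]} has zero tissue mass")
        vals.append(float(pp.pp[m].sum()) / roi_mass)
    vals = np.asarray(vals)
    return RegionalPerfusion(values=vals / vals.sum(), method=method, timepoint=timepoint)


def accumulation_table(
    pre_contrast_decomps: list[DecompositionResult],
    aeration_labels: dict[str, np.ndarray],
    times_h: list[float],
) -> pd.DataFrame:
    """Mean VNC and iodine HU per aeration region for pre-contrast scans.

    One row per (time, region, image); trend testing on the result is
    delegated to standard repeated-measures tooling.
    """
    if len(pre_contrast_decomps) != len(times_h):
        raise ValueError("need one acquisition time per decomposition")
    rows = []
    for t, dec in zip(times_h, pre_contrast_decomps):
        for region, mask in aeration_labels.items():
            mask = np.asarray(mask).astype(bool)
            rows.append({"time_h": t, "region": region, "image": "VNC",
                         "mean_hu": float(dec.vnc[mask].mean())})
            rows.append({"time_h": t, "region": region, "image": "iodine",
                         "mean_hu": float(dec.iodine[mask].mean())})
    return pd.DataFrame(rows)


_PROFILE_AXES = {"ventrodorsal": 1, "caudocranial": 2}


def vq_profiles(dv: VentilationMap, pp: PerfusionMap, axis: str) -> pd.DataFrame:
    """Paired ventilation/perfusion profiles along a body axis.

    dV and the perfusion fractions are summed per slice (raw, not
    mass-normalized) and each profile is normalized to sum 1.
    """
    if axis not in _PROFILE_AXES:
        raise ValueError(f"axis must be one of {sorted(_PROFILE_AXES)}")
    ax = _PROFILE_AXES[axis]
    require_same_grid(dv.grid, pp.grid)
    sum_axes = tuple(a for a in range(3) if a != ax)
    dv_prof = np.where(dv.mask, dv.dv, 0.0).sum(axis=sum_axes)
    pp_prof = pp.pp.sum(axis=sum_axes)
    dv_prof = dv_prof / dv_prof.sum()
    pp_prof = pp_prof / pp_prof.sum()
    return pd.DataFrame({"slice": np.arange(dv.grid.shape[ax]), "dv": dv_prof, "pp": pp_prof,
                         "axis": axis, "normalization": "raw_sum"})


VQ_SHUNT = 1
VQ_MATCHED = 2
VQ_DEAD_SPACE = 3


def vq_classify(
    dv: VentilationMap,
    pp: PerfusionMap,
    ratio_bounds: tuple[float, float] = (0.5, 2.0),
) -> np.ndarray:
    """Classify voxels into shunt-like / matched / dead-space-like regions.

    Both maps are sum-normalized over the analysis mask; the ratio
    R = dv_norm / pp_norm is thresholded: R > upper marks ventilated but
    poorly perfused (dead-space-like) lung, R < lower perfused but poorly
    ventilated (shunt-like) lung.  Outside the mask the label is 0.
    """
    lower, upper = ratio_bounds
    if not 0 <= lower < upper:
        raise ValueError("ratio_bounds must satisfy 0 <= lower < upper")
    require_same_grid(dv.grid, pp.grid)
    mask = dv.mask & pp.parenchyma
    dvn = np.where(mask & (dv.dv > 0), dv.dv, 0.0)
    dvn = dvn / dvn.sum() if dvn.sum() > 0 else dvn
    ppn = np.where(mask, pp.pp, 0.0)
    ppn = ppn / ppn.sum() if ppn.sum() > 0 else ppn

    out = np.zeros(dv.grid.shape, dtype=np.int8)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ppn > 0, dvn / np.where(ppn > 0, ppn, 1.0), np.inf)
    ratio = np.where((ppn == 0) & (dvn == 0), 1.0, ratio)  # no flow, no gas: matched
    out[mask] = VQ_MATCHED
    out[mask & (ratio > upper)] = VQ_DEAD_SPACE
    out[mask & (ratio < lower)] = VQ_SHUNT
    return out
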