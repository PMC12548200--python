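"""Digital thorax phantom with known ventilation/perfusion ground truth.

The phantom emulates the porcine two-lung / one-lung ventilation preparation
on which the downstream pipeline is validated: two ellipsoidal lungs with a
ventro-dorsal aeration gradient and a dorsally weighted perfusion
distribution, an intrapulmonary airway and vessel structure, an analytic
axial expansion linking end-expiratory (ee) to end-inspiratory (ei) geometry,
a dual-energy forward model consistent with a known voxelwise iodine
concentration field, and multinomial microsphere deposition aggregated into
12 mm tissue cubes.

Scenarios
---------
TLV   two-lung ventilation: both lungs ventilate and perfusion is split
      symmetrically.
OLV   left-sided one-lung ventilation: the right lung neither ventilates nor
      expands (gas fractions frozen at end-expiration) and hypoxic
      vasoconstriction shifts ``perfusion_shift`` of total perfusion to the
      left lung.

All gas-fraction fields taper smoothly (smootherstep of the interior
Euclidean distance, ~5 voxel band) to zero at the pleural boundary, so both
static renders are continuous images; the ventilation ground truth is
``dv = (expansion_factor - 1) * taper`` inside the ventilated lung.  The
displacement field is an analytic axial scaling about a basal plane, whose
Jacobian determinant equals ``expansion_factor`` at every ventilated-lung
voxel and 1 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .dect import DualEnergyScan
from .grid import CTVolume, Grid

__all__ = [
    "BACKGROUND",
    "LEFT_LUNG",
    "RIGHT_LUNG",
    "AIRWAY",
    "VESSEL",
    "COLOR_GAINS",
    "CUBE_EDGE_MM",
    "SOFT_TISSUE_HU",
    "PhantomConfig",
    "PhantomTruth",
    "make_phantom",
    "render_dect",
    "render_static_ct",
    "simulate_microspheres",
]

BACKGROUND = 0
LEFT_LUNG = 1
RIGHT_LUNG = 2
AIRWAY = 3
VESSEL = 4

SOFT_TISSUE_HU = 40.0
CUBE_EDGE_MM = 12.0

# fixed fluorometer gain per microsphere color (arbitrary units per sphere);
# colors are interchangeable up to this scalar
COLOR_GAINS = {
    "blue": 1.00,
    "blue-green": 1.30,
    "yellow-green": 0.90,
    "scarlet": 1.10,
    "red": 1.20,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Protocol constants and scene parameters of the synthetic thorax.

    The defaults are the desk-scale study conditions: a 64^3 grid at 3 mm
    isotropic spacing (the in-vivo protocol used ~330 mm fields at 1 mm^3;
    the 12 mm cube / voxel hierarchy is preserved), 15 000 microspheres
    (scaled from ~1.5e6 administered in vivo), iodine ratio 1.46.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    scenario: str = "TLV"
    perfusion_shift: float = 0.5  # left-lung share of total perfusion
    iodine_gain_hu_per_mgml: float = 25.0
    iodine_ratio: float = 1.46
    noise_sd_hu: float = 5.0
    n_microspheres: int = 15_000
    expansion_factor: float = 1.15
    seed: int = 0
    # secondary scene parameters
    iodine_total_mg: float = 350.0
    vessel_iodine_mgml: float = 8.0
    gas_fraction_ventral: float = 0.75
    aeration_gradient: float = 0.30
    perfusion_gradient: float = 1.0
    taper_width_vox: float = 5.0
    weight_noise_sd: float = 0.02
    fluorescence_noise_sd: float = 0.05
    residual_iodine_hu: float = 0.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError("grid too small to contain two lungs (all axes must be >= 16)")
        if self.scenario not in ("TLV", "OLV"):
            raise ValueError(f"scenario must be TLV or OLV, got {self.scenario!r}")
        if not 0.0 < self.perfusion_shift < 1.0:
            raise ValueError("perfusion_shift must lie strictly in (0, 1)")
        if not self.iodine_ratio > 1.0:
            raise ValueError("iodine_ratio must exceed 1")
        if not self.expansion_factor > 1.0:
            raise ValueError("expansion_factor must exceed 1")
        if self.n_microspheres < 1:
            raise ValueError("n_microspheres must be >= 1")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")

    @property
    def grid(self) -> Grid:
        return Grid(shape=tuple(self.grid_shape), spacing=tuple(self.voxel_size_mm))


@dataclass
class PhantomTruth:
    """Ground truth for every quantity the pipeline estimates."""

    grid: Grid
    labels: np.ndarray
    gas_fraction_ee: np.ndarray
    gas_fraction_ei: np.ndarray           # end-inspiratory geometry
    gas_fraction_ei_at_ee: np.ndarray     # material field pulled back to ee grid
    gas_fraction_mlv: np.ndarray          # mean-lung-volume surrogate on the ee grid
    iodine_concentration: np.ndarray      # mg/ml
    perfusion_fraction: np.ndarray        # sums to 1 over parenchyma
    displacement_field: np.ndarray        # (x,y,z,3) mm, ee -> ei
    jacobian: np.ndarray                  # |J| of the analytic field
    dv: np.ndarray                        # ventilation ground truth at ee geometry
    scenario: str
    config: PhantomConfig

    @property
    def lung_mask(self) -> np.ndarray:
        """Whole lung region including airway and vessel structures."""
        return self.labels > 0

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return (self.labels == LEFT_LUNG) | (self.labels == RIGHT_LUNG)

    @property
    def left_mask(self) -> np.ndarray:
        return self.labels == LEFT_LUNG

    @property
    def right_mask(self) -> np.ndarray:
        return self.labels == RIGHT_LUNG

    @property
    def ventilated_mask(self) -> np.ndarray:
        if self.scenario == "OLV":
            return self.lung_mask & self._left_region()
        return self.lung_mask

    def _left_region(self) -> np.ndarray:
        mid = (self.grid.shape[0] - 1) / 2.0
        idx = np.arange(self.grid.shape[0])[:, None, None]
        return np.broadcast_to(idx > mid, self.labels.shape)

    @property
    def tissue_density(self) -> np.ndarray:
        """True tissue density (g/ml) at the mean-lung-volume geometry."""
        rho = np.full(self.grid.shape, 1.0 + SOFT_TISSUE_HU / 1000.0)
        rho[self.lung_mask] = 1.0 - self.gas_fraction_mlv[self.lung_mask]
        return rho

    @property
    def tidal_gas_volume_ml(self) -> float:
        """True tidal gas-volume change, ml."""
        return float(self.dv.sum() * self.grid.voxel_volume_ml)

    def regional_truth(self, roi_labels: np.ndarray, codes: tuple[int, ...]) -> np.ndarray:
        """Mass-normalized regional perfusion fractions (sum to 1).

        For each ROI code, perfusion per unit tissue mass over the
        parenchyma, renormalized across the ROIs — the quantity both the
        DECT and the microsphere branch estimate.
        """
        rho = self.tissue_density
        vals = []
        for code in codes:
            m = (roi_labels == code) & self.parenchyma_mask
            mass = float((rho[m]).sum()) * self.grid.voxel_volume_ml
            if mass <= 0:
                raise ValueError(f"ROI {code} has zero parenchymal mass")
            vals.append(float(self.perfusion_fraction[m].sum()) / mass)
        vals = np.asarray(vals)
        return vals / vals.sum()


def _smootherstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (6.0 * x - 15.0) + 10.0)


def _build_labels(config: PhantomConfig) -> tuple[np.ndarray, dict]:
    n0, n1, n2 = config.grid_shape
    i, j, k = np.meshgrid(
        np.arange(n0), np.arange(n1), np.arange(n2), indexing="ij"
    )
    mid = (n0 - 1) / 2.0
    offset = 0.19 * n0
    centers = {"right": mid - offset, "left": mid + offset}
    semi = (0.145 * n0, 0.19 * n1, 0.28 * n2)
    jc = (n1 - 1) / 2.0
    kc = 0.42 * n2

    labels = np.zeros(config.grid_shape, dtype=np.int16)
    geo = {"jc": jc, "kc": kc, "semi": semi, "centers": centers}
    for side, code in (("right", RIGHT_LUNG), ("left", LEFT_LUNG)):
        ic = centers[side]
        inside = (
            ((i - ic) / semi[0]) ** 2
            + ((j - jc) / semi[1]) ** 2
            + ((k - kc) / semi[2]) ** 2
        ) <= 1.0
        labels[inside] = code
        # central airway: axial cylinder through the lower half of the lung
        r_air = max(0.02 * n0, 1.2)
        airway = (
            ((i - ic) ** 2 + (j - jc) ** 2 <= r_air**2)
            & (k <= kc)
            & inside
        )
        labels[airway] = AIRWAY
        # vessel: axial cylinder offset dorsally
        jv = jc + 0.09 * n1
        vessel = (
            ((i - ic) ** 2 + (j - jv) ** 2 <= r_air**2)
            & (k <= kc + 0.1 * n2)
            & inside
        )
        labels[vessel] = VESSEL
    if not (labels == LEFT_LUNG).any() or not (labels == RIGHT_LUNG).any():
        raise ValueError("grid too small to contain two lungs")
    return labels, geo


def make_phantom(config: PhantomConfig) -> PhantomTruth:
    """Construct the phantom ground truth (deterministic; no RNG draws)."""
    grid = config.grid
    labels, geo = _build_labels(config)
    region = labels > 0
    parenchyma = (labels == LEFT_LUNG) | (labels == RIGHT_LUNG)

    # smooth interior taper: 0 at the pleural boundary, 1 deep inside
    edt = ndimage.distance_transform_edt(region)
    taper = _smootherstep(edt / config.taper_width_vox)

    # ventro-dorsal coordinates within the lung bounding box
    n1 = config.grid_shape[1]
    j = np.arange(n1)[None, :, None]
    jc, ay = geo["jc"], geo["semi"][1]
    dorsal = np.clip((j - (jc - ay)) / (2.0 * ay), 0.0, 1.0)
    dorsal = np.broadcast_to(dorsal, config.grid_shape)

    base_aeration = config.gas_fraction_ventral - config.aeration_gradient * dorsal
    gas_ee = np.where(region, taper * base_aeration, 0.0)
    gas_ee = np.clip(gas_ee, 0.0, 1.0)

    # ventilated side(s)
    mid = (config.grid_shape[0] - 1) / 2.0
    left_region = (np.arange(config.grid_shape[0])[:, None, None] > mid) & region
    ventilated = left_region if config.scenario == "OLV" else region

    s = config.expansion_factor
    dv = np.where(ventilated, (s - 1.0) * taper, 0.0)
    gas_ei_at_ee = np.where(ventilated, (gas_ee + dv) / s, gas_ee)
    gas_ei_at_ee = np.where(region, gas_ei_at_ee, 0.0)
    gas_mlv = np.where(region, 0.5 * (gas_ee + gas_ei_at_ee), 0.0)

    # analytic axial expansion about a basal plane two voxels below the lungs
    ks = np.nonzero(region.any(axis=(0, 1)))[0]
    k_base = int(ks.min()) - 2
    z0 = k_base * grid.spacing[2] + grid.origin[2]
    footprint = ventilated.any(axis=2)
    zw = (np.arange(config.grid_shape[2]) * grid.spacing[2] + grid.origin[2])[None, None, :]
    uz = np.where(footprint[:, :, None], (s - 1.0) * np.maximum(0.0, zw - z0), 0.0)
    displacement = np.zeros(tuple(config.grid_shape) + (3,))
    displacement[..., 2] = uz

    jac = np.where(ventilated, s, 1.0)

    # perfusion: dorsally weighted, tapered, scenario-dependent left/right split
    # perfusion_shift sets the left-lung share under both scenarios (0.5 =
    # symmetric TLV baseline; under OLV hypoxic vasoconstriction raises it)
    w = np.where(parenchyma, taper * (1.0 + config.perfusion_gradient * dorsal), 0.0)
    perf = np.zeros(config.grid_shape)
    left_p = parenchyma & left_region
    right_p = parenchyma & ~left_region
    perf[left_p] = config.perfusion_shift * w[left_p] / w[left_p].sum()
    perf[right_p] = (1.0 - config.perfusion_shift) * w[right_p] / w[right_p].sum()

    iodine = np.zeros(config.grid_shape)
    iodine[parenchyma] = (
        config.iodine_total_mg * perf[parenchyma] / grid.voxel_volume_ml
    )
    iodine[labels == VESSEL] = config.vessel_iodine_mgml

    truth = PhantomTruth(
        grid=grid,
        labels=labels,
        gas_fraction_ee=gas_ee,
        gas_fraction_ei=np.zeros(config.grid_shape),
        gas_fraction_ei_at_ee=gas_ei_at_ee,
        gas_fraction_mlv=gas_mlv,
        iodine_concentration=iodine,
        perfusion_fraction=perf,
        displacement_field=displacement,
        jacobian=jac,
        dv=dv,
        scenario=config.scenario,
        config=config,
    )
    truth.gas_fraction_ei = _warp_to_ei(truth, k_base)[0]
    return truth


def _warp_to_ei(truth: PhantomTruth, k_base: int) -> tuple[np.ndarray, np.ndarray]:
    """End-inspiratory gas fraction field and lung mask on the image grid.

    Every ei-grid voxel is pulled back through the analytic inverse of the
    axial expansion and the (smooth) material gas-fraction field is sampled
    with cubic splines; the warped lung mask uses nearest-neighbour lookup.
    """
    cfg = truth.config
    grid = truth.grid
    s = cfg.expansion_factor
    z0 = k_base * grid.spacing[2] + grid.origin[2]

    ventilated = truth.ventilated_mask
    footprint = ventilated.any(axis=2)

    n0, n1, n2 = grid.shape
    i, j, k = np.meshgrid(np.arange(n0), np.arange(n1), np.arange(n2), indexing="ij")
    zw = k * grid.spacing[2] + grid.origin[2]
    in_col = footprint[:, :, None] & np.broadcast_to(zw > z0, k.shape)
    z_src = np.where(in_col, z0 + (zw - z0) / s, zw)
    k_src = (z_src - grid.origin[2]) / grid.spacing[2]

    material = truth.gas_fraction_ei_at_ee
    warped = ndimage.map_coordinates(
        material, [i.astype(float), j.astype(float), k_src], order=3, mode="nearest"
    )
    region = truth.lung_mask.astype(np.int8)
    mask_w = (
        ndimage.map_coordinates(region, [i, j, np.rint(k_src).astype(int)], order=0) > 0
    )
    warped = np.where(mask_w, np.clip(warped, 0.0, 1.0), 0.0)
    return warped, mask_w


def render_static_ct(truth: PhantomTruth, phase: str) -> CTVolume:
    """Render a static breath-hold CT (HU) at end-expiration or end-inspiration."""
    if phase == "ee":
        hu = np.where(truth.lung_mask, -1000.0 * truth.gas_fraction_ee, SOFT_TISSUE_HU)
    elif phase == "ei":
        ks = np.nonzero(truth.lung_mask.any(axis=(0, 1)))[0]
        warped, mask_w = _warp_to_ei(truth, int(ks.min()) - 2)
        hu = np.where(mask_w, -1000.0 * warped, SOFT_TISSUE_HU)
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'ee' or 'ei'")
    return CTVolume(hu=hu, grid=truth.grid, phase=phase)


def render_dect(
    truth: PhantomTruth,
    config: PhantomConfig | None = None,
    rng: np.random.Generator | None = None,
    pre_contrast: bool = False,
) -> DualEnergyScan:
    """Forward dual-energy render at mean-lung-volume geometry.

    HU_high = VNC + g*C and HU_low = VNC + r*g*C with g the iodine gain, r
    the iodine ratio and C the iodine concentration; independent Gaussian
    noise of sd ``noise_sd_hu`` is added per spectrum.  ``pre_contrast``
    renders the scan acquired just before contrast injection (iodine limited
    to any configured residual enhancement).
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    vnc_true = np.where(
        truth.lung_mask, -1000.0 * truth.gas_fraction_mlv, SOFT_TISSUE_HU
    )
    g = config.iodine_gain_hu_per_mgml
    if pre_contrast:
        enh = np.where(truth.parenchyma_mask, config.residual_iodine_hu, 0.0)
    else:
        enh = g * truth.iodine_concentration
    hu_high = vnc_true + enh
    hu_low = vnc_true + config.iodine_ratio * enh
    if config.noise_sd_hu > 0:
        hu_low = hu_low + rng.normal(0.0, config.noise_sd_hu, size=hu_low.shape)
        hu_high = hu_high + rng.normal(0.0, config.noise_sd_hu, size=hu_high.shape)
    return DualEnergyScan(hu_low=hu_low, hu_high=hu_high, grid=truth.grid)


def _cube_index(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Flat cube id per voxel for the 12 mm cube grid anchored at the origin."""
    per_axis = []
    n_cubes = []
    for ax in range(3):
        world = np.arange(grid.shape[ax]) * grid.spacing[ax] + grid.origin[ax]
        c = np.floor(world / CUBE_EDGE_MM).astype(int)
        c -= c.min()
        per_axis.append(c)
        n_cubes.append(c.max() + 1)
    ci, cj, ck = np.meshgrid(*per_axis, indexing="ij")
    flat = (ci * n_cubes[1] + cj) * n_cubes[2] + ck
    return flat, np.array(n_cubes)


def simulate_microspheres(
    truth: PhantomTruth,
    config: PhantomConfig | None = None,
    rng: np.random.Generator | None = None,
    color: str | None = None,
) -> pd.DataFrame:
    """Deposit microspheres in proportion to perfusion and cut 12 mm cubes.

    Spheres are drawn multinomially over parenchymal voxels with
    probabilities equal to the perfusion fractions, then aggregated into
    axis-aligned 12 mm cubes.  Per cube the fluorescence is
    ``counts * color_gain * lognormal`` and the weight is the parenchymal
    tissue mass perturbed by Gaussian noise.  A cube belongs to the lung
    when at least half of its voxels are parenchyma.
    """
    config = config or truth.config
    if config.n_microspheres < 1:
        raise ValueError("n_microspheres must be >= 1")
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    if color is None:
        color = str(rng.choice(sorted(COLOR_GAINS)))
    if color not in COLOR_GAINS:
        raise ValueError(f"unknown microsphere color {color!r}")

    grid = truth.grid
    parenchyma = truth.parenchyma_mask
    p = truth.perfusion_fraction[parenchyma]
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("perfusion_fraction must sum to 1 over the parenchyma")
    counts_flat = rng.multinomial(config.n_microspheres, p / total)
    counts = np.zeros(grid.shape, dtype=np.int64)
    counts[parenchyma] = counts_flat

    cube_of, n_cubes = _cube_index(grid)
    n_total = int(np.prod(n_cubes))
    flat = cube_of.ravel()
    cube_counts = np.bincount(flat, weights=counts.ravel(), minlength=n_total)
    cube_capacity = np.bincount(flat, minlength=n_total)
    cube_parenchyma = np.bincount(flat, weights=parenchyma.ravel(), minlength=n_total)
    rho = truth.tissue_density
    mass_g = np.where(parenchyma, rho, 0.0) * grid.voxel_volume_ml
    cube_mass_g = np.bincount(flat, weights=mass_g.ravel(), minlength=n_total)

    keep = cube_parenchyma >= 1
    ids = np.nonzero(keep)[0]
    ci = ids // (n_cubes[1] * n_cubes[2])
    cj = (ids // n_cubes[2]) % n_cubes[1]
    ck = ids % n_cubes[2]
    # cube grid is anchored at the image origin
    base = np.floor(np.asarray(grid.origin) / CUBE_EDGE_MM)
    centers = (np.stack([ci, cj, ck], axis=1) + base + 0.5) * CUBE_EDGE_MM

    n = ids.size
    weight_noise = rng.normal(0.0, config.weight_noise_sd, size=n) if config.weight_noise_sd > 0 else np.zeros(n)
    if config.fluorescence_noise_sd > 0:
        sd = config.fluorescence_noise_sd
        fl_noise = np.exp(rng.normal(-0.5 * sd * sd, sd, size=n))
    else:
        fl_noise = np.ones(n)

    weight_mg = np.maximum(cube_mass_g[ids] * 1000.0 * (1.0 + weight_noise), 0.0)
    fluorescence = cube_counts[ids] * COLOR_GAINS[color] * fl_noise

    return pd.DataFrame(
        {
            "cube_x_mm": centers[:, 0],
            "cube_y_mm": centers[:, 1],
            "cube_z_mm": centers[:, 2],
            "weight_mg": weight_mg,
            "color": color,
            "fluorescence_au": fluorescence,
            "is_lung": cube_parenchyma[ids] >= 0.5 * cube_capacity[ids],
            "n_spheres": cube_counts[ids].astype(int),
        }
    )
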