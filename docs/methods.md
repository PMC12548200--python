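# Methods

`vqpipe` implements a pipeline for deriving regional pulmonary perfusion from
dual-energy CT (DECT), regional ventilation from paired static CT scans, and
for quantifying the agreement of the DECT perfusion surrogate against
microsphere-derived blood flow. Because the in-vivo data such pipelines are
built for are rarely shareable, the package ships a digital thorax phantom
with known ground truth; every stage is validated as a recovery property on
that phantom.

## Dual-energy decomposition

A dual-energy acquisition measures each voxel under two X-ray spectra.
Iodine attenuates more strongly at low energy by the *iodine ratio* r, so
with V the virtual non-contrast (VNC) value and I the iodine enhancement in
high-energy HU:

    HU_low  = V + r I
    HU_high = V + I        =>   I = (HU_low - HU_high) / (r - 1),  V = HU_high - I

The default r = 1.46 corresponds to a split-filter (Twin Beam) scanner with
modest spectral separation. The per-voxel solve amplifies independent
per-spectrum noise σ to sd(I) = σ√2 / (r − 1), which the tests verify to
10%. Vendor decompositions add a proprietary "minimal-noise" objective; this
implementation exposes an optional isotropic Gaussian smoothing of the
iodine image (sigma in voxels, default 0) as its documented surrogate.
Negative iodine values are unphysical noise and are clipped by default
*except* in the tracer-accumulation analysis, where clipping would bias the
mean signal the check looks for.

## Ventilation

Gas fraction is F_gas = HU / −1000 (air −1000 HU, water 0 HU). With a
deformable registration mapping end-expiratory (ee) coordinates to
end-inspiratory (ei) ones, x → x + u(x), the tidal gas-volume change per
voxel at ee geometry is

    dV = F_gas,ei@ee · |J| − F_gas,ee

where F_gas,ei@ee is the ei gas fraction pulled back trilinearly through the
field and |J| the Jacobian determinant of the mapping (central differences
in world mm; one-sided at the volume boundary). The registration itself is a
pluggable contract: a ground-truth passthrough engine (validation) and a
translation-initialized symmetric-forces demons registrar built on SimpleITK
(demonstration) are bundled. Everything downstream of the field is validated
with the passthrough engine — the contribution under test is the dV formula,
not any particular registrar.

Mask preparation (spherical opening radius 2, closing 15, dilation 10
voxels) uses exact Euclidean distance transforms, which is mathematically
identical to ball-structuring-element morphology and tractable at radius 15;
the equivalence is asserted against direct structuring-element morphology at
small radii in the tests. The "3×3×3 Gaussian kernel" denoising step is
interpreted as sigma 0.75 voxels truncated at a 1-voxel radius (configurable).

## Perfusion and ROIs

Assuming constant blood iodine concentration, the iodine image is
proportional to perfused blood volume per voxel. Restricted to the
parenchyma (lung minus vessels segmented by threshold region growing) and
divided by its sum, it becomes a perfusion-fraction map: the sum over an ROI
is that ROI's share of total perfused blood volume. Regional analysis uses
three ROIs: the right lung and the left lung split along the caudo-cranial
axis into two equal-volume parts. The split scans slices from the cranial
end and places the boundary at the first slice whose cumulative voxel count
strictly exceeds half, so the crossing slice goes caudal. Per ROI the value
is (Σ pp)/(Σ mass) — mass from the VNC image via the water-equivalent
density ρ = 1 + HU/1000 g/ml, clipped to [0, 1.1] — renormalized over the
three ROIs. Normalizing at ROI level (ratio of sums) avoids dividing by
near-zero voxel masses. An alternative normalization against a blood-pool
reference region is available but not the default.

V/Q summaries: per-slice profiles of dV and perfusion along the
ventro-dorsal or caudo-cranial axis (raw sums, each normalized to 1), and a
voxel classification by the ratio of sum-normalized dV to perfusion into
shunt-like (< 0.5), matched, and dead-space-like (> 2) regions.

## Microsphere branch

Fluorescent 15 µm microspheres lodge in capillaries in proportion to flow;
the dried lung is cut into 12 mm cubes, each weighed and fluorometered.
Per-cube fluorescence divided by weight is flow per unit tissue mass.
Regional flow is the ratio of summed fluorescence to summed weight per ROI,
renormalized across the three ROIs — the same intensive flow-per-mass
quantity the DECT branch reports, which is what makes the two methods
directly comparable; a per-cube sum-normalized aggregate is also available.
Cubes are assigned to ROIs by their center point (postmortem cubes lose
anatomic registration in vivo; the phantom sidesteps this by sharing one
coordinate frame, and that limitation does not exercise the in-vivo
cube-to-ROI mapping problem). Cube-center assignment and the ≥50%-parenchyma
lung-cube rule introduce a small deterministic geometric bias (≲0.005 in
ROI fractions at this phantom geometry, measured at n = 10⁶ spheres), mostly
where cubes straddle the cranial/caudal split plane.

## Agreement battery

On rows (animal, timepoint, condition, ROI, PP_FLM, PP_DECT), where each
method's three ROI fractions sum to 1 per scan: OLS regression of PP_DECT on
PP_FLM (slope, intercept, adjusted R² = 1 − (1 − R²)(n−1)/(n−2), slope
t-test p); Bland–Altman bias and limits of agreement bias ± 1.96·sd(d) with
sample sd; and quadrant concordance of between-consecutive-timepoint
changes. Concordance counts the change pairs in which both methods move in
the same direction (quadrants I and III) as a percentage of all nonzero
change pairs; the literal (I+III)/(II+IV) ratio is also exposed, since both
readings circulate, but only the all-quadrant form is a bounded percentage.
Exact-zero changes carry no direction and are excluded (and counted).
Changes are labeled with the source timepoint's condition, so the TLV
stratum holds the TLV→OLV transitions. The stratified report covers
{TLV, OLV} × all and all × {cranial, caudal, right}, plus the pooled row.
Note that the per-scan sum-to-one constraint forces the pooled Bland–Altman
bias to zero by construction; the ROI-stratified biases are the informative
ones.

## The phantom

The phantom is the package's study condition generator, not a test fixture:

- **Geometry.** 64³ voxels at 3 mm isotropic spacing (in vivo: ~330 mm
  fields at 1 mm³; the coarser grid keeps an end-to-end study under ten
  seconds while preserving the 12 mm cube / voxel hierarchy, since 12 mm =
  4 voxels). Two mirror-symmetric ellipsoidal lungs, each with an axial
  airway and a dorsally offset vessel; axis conventions are right→left,
  ventral→dorsal, caudal→cranial.
- **Aeration.** End-expiratory gas fraction 0.75 ventral falling linearly to
  0.45 dorsal, multiplied by a smootherstep taper of the interior distance
  (5-voxel band) so the field reaches zero continuously at the pleura.
  A hard lung/soft-tissue edge would put O(0.1) trilinear-interpolation
  errors in the boundary shell and defeat the dV recovery bound; the taper
  is the design decision that makes sub-0.01 voxelwise recovery a fair test.
  Airway and vessel voxels share the lung gas-fraction field for the same
  continuity reason (they differ in labels and iodine only).
- **Breathing.** The ee→ei map is an analytic axial scaling about a basal
  plane two voxels below the lungs, applied over the ventilated lung's
  column footprint: |J| equals the expansion factor (default 1.15,
  a moderate tidal volume at these lung sizes) at every ventilated voxel and
  1 elsewhere. Ventilation truth is dv = (s − 1)·taper; the ei-geometry
  image is rendered by pulling the material field back through the exact
  inverse map with cubic interpolation. Under OLV the right lung is frozen
  (no ventilation, no expansion).
- **Perfusion.** Dorsally weighted (1 + dorsal fraction, i.e. 2:1
  dorsal:ventral) within each lung, tapered, and split between lungs by
  `perfusion_shift` (left-lung share): 0.5 at TLV; under OLV the default
  schedule uses 0.70, 0.76, 0.82, 0.88, emulating hypoxic vasoconstriction
  plus increasing inhaled-NO doses acting on the ventilated lung. The
  pipeline adds a per-animal baseline shift offset (sd 0.03) for
  inter-animal variability. Iodine concentration is proportional to
  perfusion fraction (total 350 mg reaching the lung; only the product of
  gain and concentration matters downstream, and sum normalization removes
  even that). Vessels carry a blood-pool concentration of 8 mg/ml, i.e.
  200 HU enhancement at the default gain of 25 HU/(mg/ml), which is what the
  threshold region-growing segmentation keys on.
- **DECT render.** At mean-lung-volume geometry, approximated as the ee grid
  with the average of ee and ei gas fractions (registering a third geometry
  is not the object under test). Independent Gaussian noise per spectrum,
  default sd 5 HU — a 1 mm-voxel lung noise level of ~25 HU scaled by the
  27-fold voxel-volume increase.
- **Microspheres.** 15 000 spheres (scaled from ~1.5×10⁶ administered in
  vivo) drawn multinomially over parenchymal voxels with perfusion-fraction
  probabilities, aggregated into origin-anchored 12 mm cubes. A cube is a
  lung cube if ≥50% of its voxels are parenchyma. Cube weight is the
  parenchymal tissue mass perturbed by 2% Gaussian noise; fluorescence is
  count × color gain × mean-one lognormal noise (sd 5%); the five colors
  differ only by a fixed gain scalar and one is chosen at random per
  injection. Sphere counts always total exactly n.
- **Randomness.** All draws come from `numpy` generators seeded with
  documented key tuples (seed, animal, timepoint, purpose), so every render
  and table is bit-reproducible for a fixed seed.

## What the phantom does and does not show

Passing recovery tests on this phantom demonstrates the internal
consistency and correctness of the computational chain: exact decomposition
inversion, correct Jacobian and resampling in the dV formula, correct
normalization and ROI bookkeeping, correct agreement statistics. It does
*not* exercise real-scanner effects (beam hardening, cardiac motion,
spectral miscalibration, registration failure on real texture), real
lung anatomy, the postmortem cube-to-ROI mapping problem, or the
density-dependent decomposition errors the in-vivo comparison attributes
systematic overestimation to. The default-noise study reports a slope below
unity — an attenuation produced mainly by negative-iodine clipping at low
signal, which is a real property of the processing chain, not a
reproduction of in-vivo biases.

## Problem sizes and numerical choices

Default problem sizes (64³ grid, 15 000 spheres, 3 animals × 5 timepoints)
run the whole study in seconds; the large-n microsphere convergence check
uses 10⁶ spheres. Tolerances used in validation: decomposition round trip
1e-9 HU; Jacobian of affine fields 1e-6; dV voxelwise RMSE 0.01 and tidal
volume 3% (discretization of the warped render); regional DECT recovery
1e-2 absolute; microsphere ROI fractions 3 binomial SEs of their exact
multinomial expectation. Degenerate inputs (zero iodine in mask, empty
masks, zero-variance regressors, all-tied change series, non-positive cube
weights) raise informative errors or warnings rather than propagating NaNs.
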