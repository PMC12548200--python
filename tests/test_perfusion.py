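"""Perfusion maps, ROI construction, accumulation table and V/Q summaries."""

import numpy as np
import pandas as pd
import pytest

from vqpipe.dect import DecompositionResult, DecompositionConfig, decompose
from vqpipe.grid import Grid
from vqpipe.perfusion import (
    ROI_CODES,
    ROI_LEFT_CAUDAL,
    ROI_LEFT_CRANIAL,
    ROI_RIGHT,
    PerfusionMap,
    accumulation_table,
    perfusion_map,
    regional_perfusion,
    segment_vessels,
    split_rois,
    tissue_mass,
    vq_classify,
    vq_profiles,
)
from vqpipe.phantom import render_dect
from vqpipe.ventilation import VentilationMap


class TestSegmentVessels:
    def _tube_phantom(self):
        g = Grid((24, 24, 24), (1.0, 1.0, 1.0))
        hu = np.full(g.shape, -700.0)
        tube = np.zeros(g.shape, dtype=bool)
        tube[10:14, 10:14, 4:20] = True
        hu[tube] = 300.0
        return g, hu, tube

    def test_grows_exactly_the_bright_tube(self):
        g, hu, tube = self._tube_phantom()
        seed = np.array([[11.0, 11.0, 10.0]])
        mask = segment_vessels(hu, g, seed, threshold_hu=-200.0)
        assert np.array_equal(mask, tube)

    def test_threshold_above_global_max_fails(self):
        g, hu, _ = self._tube_phantom()
        with pytest.raises(ValueError, match="below threshold"):
            segment_vessels(hu, g, np.array([[11.0, 11.0, 10.0]]), threshold_hu=400.0)

    def test_seed_outside_volume_rejected(self):
        g, hu, _ = self._tube_phantom()
        with pytest.raises(ValueError, match="outside"):
            segment_vessels(hu, g, np.array([[99.0, 0.0, 0.0]]), threshold_hu=-200.0)


class TestTissueMass:
    @pytest.mark.parametrize(
        "hu, voxel_ml, mass_g",
        [(-700.0, 0.027, 0.3 * 0.027), (-1000.0, 0.027, 0.0), (0.0, 1.0, 1.0)],
    )
    def test_water_equivalent_density(self, hu, voxel_ml, mass_g):
        out = tissue_mass(np.full((2, 2, 2), hu), voxel_ml)
        assert out == pytest.approx(np.full((2, 2, 2), mass_g))

    def test_density_clipped_at_1p1(self):
        assert tissue_mass(np.array([500.0]), 1.0)[0] == pytest.approx(1.1)


class TestPerfusionMap:
    def test_uniform_iodine_gives_uniform_fractions(self):
        g = Grid((8, 8, 8))
        mask = np.zeros(g.shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        pm = perfusion_map(np.full(g.shape, 5.0), g, mask)
        assert pm.pp[mask] == pytest.approx(1.0 / mask.sum())
        assert pm.pp[~mask].sum() == 0

    def test_scale_invariance(self, rng):
        g = Grid((8, 8, 8))
        mask = rng.random(g.shape) > 0.5
        iod = rng.random(g.shape)
        a = perfusion_map(iod, g, mask)
        b = perfusion_map(3.7 * iod, g, mask)
        assert np.allclose(a.pp, b.pp)

    def test_zero_iodine_is_degenerate(self):
        g = Grid((4, 4, 4))
        with pytest.raises(ValueError, match="normalize"):
            perfusion_map(np.zeros(g.shape), g, np.ones(g.shape, dtype=bool))

    def test_phantom_roi_fractions_match_generator(self, olv_truth):
        """Noise-free DECT iodine reproduces the generator's ROI perfusion."""
        dec = decompose(render_dect(olv_truth))
        vessels = olv_truth.labels == 4
        pm = perfusion_map(dec.iodine, olv_truth.grid, olv_truth.parenchyma_mask, vessels)
        rois = split_rois(olv_truth.left_mask, olv_truth.right_mask, olv_truth.grid)
        for code in ROI_CODES:
            got = pm.pp[rois.mask(code)].sum()
            want = olv_truth.perfusion_fraction[rois.mask(code) & olv_truth.parenchyma_mask].sum()
            assert got == pytest.approx(want, abs=1e-3)


class TestSplitRois:
    def _mask_from_counts(self, counts_cranial_first, shape=(6, 6, None)):
        n = len(counts_cranial_first)
        g = Grid((6, 6, n))
        left = np.zeros(g.shape, dtype=bool)
        for pos, c in enumerate(counts_cranial_first):
            k = n - 1 - pos  # cranial = high index
            left[0, :c, k] = True
        return g, left

    def test_equal_slices_split_in_half(self):
        g, left = self._mask_from_counts([3] * 10)
        right = np.zeros(g.shape, dtype=bool)
        right[5, 0, :] = True
        rois = split_rois(left, right, g)
        assert (rois.labels == ROI_LEFT_CRANIAL).sum() == (rois.labels == ROI_LEFT_CAUDAL).sum()

    def test_uneven_slice_counts_tie_goes_caudal(self):
        """Counts (1,1,1,1,6) from the cranial end: cranial ROI = 4 voxels."""
        g, left = self._mask_from_counts([1, 1, 1, 1, 6])
        right = np.zeros(g.shape, dtype=bool)
        right[5, 0, :] = True
        rois = split_rois(left, right, g)
        assert (rois.labels == ROI_LEFT_CRANIAL).sum() == 4
        assert (rois.labels == ROI_LEFT_CAUDAL).sum() == 6

    def test_right_lung_untouched(self, truth):
        rois = split_rois(truth.left_mask, truth.right_mask, truth.grid)
        assert np.array_equal(rois.labels == ROI_RIGHT, truth.right_mask)

    def test_split_is_balanced_within_one_slice(self, truth):
        rois = split_rois(truth.left_mask, truth.right_mask, truth.grid)
        n_cr = (rois.labels == ROI_LEFT_CRANIAL).sum()
        n_ca = (rois.labels == ROI_LEFT_CAUDAL).sum()
        slice_counts = truth.left_mask.sum(axis=(0, 1))
        assert abs(int(n_cr) - int(n_ca)) <= slice_counts.max()

    def test_empty_left_mask_rejected(self):
        g = Grid((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            split_rois(np.zeros(g.shape, dtype=bool), np.ones(g.shape, dtype=bool), g)


def _three_roi_setup(pp_sums, masses):
    """One-voxel-per-ROI synthetic map for regional arithmetic checks."""
    g = Grid((3, 1, 1))
    labels = np.array([[[ROI_RIGHT]], [[ROI_LEFT_CRANIAL]], [[ROI_LEFT_CAUDAL]]])
    from vqpipe.perfusion import ROISet

    rois = ROISet(labels=labels, grid=g, split_slice=0)
    pp = PerfusionMap(pp=np.asarray(pp_sums, dtype=float).reshape(3, 1, 1),
                      parenchyma=np.ones(g.shape, dtype=bool), grid=g)
    mass = np.asarray(masses, dtype=float).reshape(3, 1, 1)
    return pp, mass, rois


class TestRegionalPerfusion:
    @pytest.mark.parametrize(
        "pp_sums, masses, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), (1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            ((0.5, 0.3, 0.2), (1, 1, 1), (0.5, 0.3, 0.2)),       # mass cancels
            ((0.5, 0.25, 0.25), (2, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
        ],
    )
    def test_ratio_of_sums_then_renormalize(self, pp_sums, masses, expected):
        pp, mass, rois = _three_roi_setup(pp_sums, masses)
        out = regional_perfusion(pp, mass, rois)
        assert out.values == pytest.approx(np.asarray(expected), abs=1e-12)

    def test_zero_mass_roi_rejected(self):
        pp, mass, rois = _three_roi_setup((0.5, 0.25, 0.25), (0, 1, 1))
        with pytest.raises(ValueError, match="zero tissue mass"):
            regional_perfusion(pp, mass, rois)

    def test_end_to_end_regional_recovery(self, olv_truth):
        """Phantom -> decompose -> map -> regional: matches truth within 1e-2."""
        dec = decompose(render_dect(olv_truth))
        vessels = olv_truth.labels == 4
        pm = perfusion_map(dec.iodine, olv_truth.grid, olv_truth.parenchyma_mask, vessels)
        mass = tissue_mass(dec.vnc, olv_truth.grid.voxel_volume_ml)
        rois = split_rois(olv_truth.left_mask, olv_truth.right_mask, olv_truth.grid)
        got = regional_perfusion(pm, mass, rois)
        want = olv_truth.regional_truth(rois.labels, ROI_CODES)
        assert got.values == pytest.approx(want, abs=1e-2)
        assert got.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestAccumulationTable:
    def _decomp(self, truth, residual=0.0):
        from dataclasses import replace

        cfg = replace(truth.config, noise_sd_hu=0.0, residual_iodine_hu=residual)
        return decompose(render_dect(truth, cfg, pre_contrast=True))

    def test_identical_spectra_give_zero_iodine_means(self, truth):
        decs = [self._decomp(truth)] * 3
        labels = {"aerated": truth.left_mask, "non_aerated": truth.right_mask}
        tab = accumulation_table(decs, labels, [0.0, 1.0, 2.0])
        iod = tab[tab["image"] == "iodine"]
        assert iod["mean_hu"].abs().max() < 1e-9

    def test_persistent_iodine_is_detected(self, truth):
        decs = [self._decomp(truth, residual=10.0)]
        labels = {"aerated": truth.left_mask, "non_aerated": truth.right_mask}
        tab = accumulation_table(decs, labels, [0.0])
        iod = tab[tab["image"] == "iodine"]
        assert iod["mean_hu"].to_numpy() == pytest.approx(10.0, abs=1e-9)

    def test_table_shape_is_2x2xT(self, truth):
        decs = [self._decomp(truth)] * 4
        labels = {"aerated": truth.left_mask, "non_aerated": truth.right_mask}
        tab = accumulation_table(decs, labels, [0.0, 1.0, 2.0, 3.0])
        assert len(tab) == 2 * 2 * 4


def _vmap_pmap(dv_vals, pp_vals, mask, g):
    vmap = VentilationMap(dv=dv_vals, mask=mask, grid=g)
    pmap = PerfusionMap(pp=pp_vals / pp_vals.sum(), parenchyma=mask, grid=g)
    return vmap, pmap


class TestVqProfiles:
    def test_proportional_fields_give_identical_profiles(self, rng):
        g = Grid((8, 8, 8))
        mask = np.ones(g.shape, dtype=bool)
        base = rng.random(g.shape)
        vmap, pmap = _vmap_pmap(2.5 * base, base.copy(), mask, g)
        prof = vq_profiles(vmap, pmap, "ventrodorsal")
        assert prof["dv"].to_numpy() == pytest.approx(prof["pp"].to_numpy())
        assert prof["dv"].sum() == pytest.approx(1.0, abs=1e-9)
        assert prof["pp"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_phantom_ventilation_exceeds_perfusion_ventrally(self, truth):
        """Uniform-ish dV against dorsally weighted perfusion: the ventral
        half of the ventro-dorsal profile is ventilation-dominant."""
        from vqpipe.dect import decompose

        dec = decompose(render_dect(truth))
        pm = perfusion_map(dec.iodine, truth.grid, truth.parenchyma_mask, truth.labels == 4)
        vmap = VentilationMap(dv=truth.dv, mask=truth.parenchyma_mask, grid=truth.grid)
        prof = vq_profiles(vmap, pm, "ventrodorsal")
        occupied = prof["pp"].to_numpy() > 0
        ventral = np.nonzero(occupied)[0][: occupied.sum() // 2]
        assert (prof["dv"].to_numpy()[ventral] >= prof["pp"].to_numpy()[ventral]).all()


class TestVqClassify:
    def test_equal_normalized_fields_are_all_matched(self, rng):
        g = Grid((8, 8, 8))
        mask = np.ones(g.shape, dtype=bool)
        base = rng.random(g.shape) + 0.1
        vmap, pmap = _vmap_pmap(base.copy(), base.copy(), mask, g)
        labels = vq_classify(vmap, pmap)
        assert np.all(labels[mask] == 2)

    def test_unperfused_ventilated_voxel_is_dead_space(self):
        g = Grid((2, 1, 1))
        mask = np.ones(g.shape, dtype=bool)
        dv = np.array([1.0, 1.0]).reshape(2, 1, 1)
        pp = np.array([0.0, 1.0]).reshape(2, 1, 1)
        vmap, pmap = _vmap_pmap(dv, pp, mask, g)
        labels = vq_classify(vmap, pmap)
        assert labels[0, 0, 0] == 3  # dead-space-like

    def test_matches_brute_force_thresholding(self, rng):
        g = Grid((16, 16, 16))
        mask = rng.random(g.shape) > 0.3
        dv = rng.random(g.shape) * mask
        pp = rng.random(g.shape) * mask
        vmap, pmap = _vmap_pmap(dv.copy(), pp.copy() + 1e-12, mask, g)
        lower, upper = 0.5, 2.0
        got = vq_classify(vmap, pmap, (lower, upper))
        dvn = np.where(mask, np.maximum(dv, 0), 0.0)
        dvn /= dvn.sum()
        ppn = np.where(mask, pmap.pp, 0.0)
        ppn /= ppn.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ppn > 0, dvn / np.where(ppn > 0, ppn, 1), np.inf)
        ratio = np.where((ppn == 0) & (dvn == 0), 1.0, ratio)
        want = np.zeros(g.shape, dtype=int)
        want[mask] = 2
        want[mask & (ratio > upper)] = 3
        want[mask & (ratio < lower)] = 1
        assert np.array_equal(got, want)

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        g = Grid((12, 12, 12))
        mask = rng.random(g.shape) > 0.4
        vmap, pmap = _vmap_pmap(rng.random(g.shape) * mask, rng.random(g.shape) * mask + 1e-12, mask, g)
        labels = vq_classify(vmap, pmap)
        assert set(np.unique(labels[mask])) <= {1, 2, 3}
        assert np.all(labels[~mask] == 0)
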