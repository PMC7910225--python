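"""Airway segmentation: thresholds, connectivity, refinement, volume."""

import numpy as np
import pytest
from scipy import ndimage

from mosaictomo.segment import (auto_cylinder_mask, extract_connected_airways,
                                intermeans_threshold, iso_threshold_slicewise,
                                mask_bone, refine_segmentation,
                                segment_airways)


@pytest.fixture(scope="module")
def rendered(foam_phantom):
    """Recon-like rendering of the phantom: slight blur plus noise."""
    rng = np.random.default_rng(0)
    vol = ndimage.gaussian_filter(foam_phantom.volume.astype(float), 1.0)
    return vol + 3.0 * rng.standard_normal(vol.shape)


class TestMaskBone:
    def test_threshold_above_max_gives_empty_mask(self, rendered):
        assert not mask_bone(rendered, rendered.max() + 1).any()

    def test_threshold_below_min_gives_full_mask(self, rendered, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="mosaictomo.segment"):
            mask = mask_bone(rendered, rendered.min() - 1)
        assert mask.all()
        assert "suspicious" in caplog.text

    def test_planted_bone_rods_recovered(self, foam_phantom, rendered):
        thr = 0.5 * (foam_phantom.mu_tissue
                     + 5 * foam_phantom.mu_tissue)  # midway tissue/bone
        mask = mask_bone(rendered, thr)
        gt = foam_phantom.bone_mask
        dice = 2 * (mask & gt).sum() / (mask.sum() + gt.sum())
        assert dice > 0.95


class TestIntermeans:
    def test_balanced_bimodal_threshold_near_midpoint(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.02, 4000),
                            rng.normal(0.8, 0.02, 4000)])
        assert intermeans_threshold(x) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            intermeans_threshold(np.full(10, 3.0))


class TestSlicewise:
    def test_thresholds_between_modes(self, foam_phantom, rendered):
        bone = mask_bone(rendered, 3 * foam_phantom.mu_tissue)
        cyl = np.broadcast_to(foam_phantom.lung_mask[0] | True,
                              rendered.shape)  # full frame
        air, thr = iso_threshold_slicewise(
            rendered, exclusion_masks=bone,
            cylinder_mask=np.broadcast_to(foam_phantom.lung_mask.any(axis=0),
                                          rendered.shape))
        mid = thr[10:-10]  # slices with substantial air
        frac = np.mean((mid > 0.2 * foam_phantom.mu_tissue)
                       & (mid < 0.8 * foam_phantom.mu_tissue))
        assert frac >= 0.95

    def test_degenerate_slice_borrows_neighbor_threshold(self):
        vol = np.random.default_rng(0).random((5, 16, 16)) * 10
        vol[2] = 5.0  # constant slice
        with pytest.warns(UserWarning, match="degenerate"):
            air, thr = iso_threshold_slicewise(vol)
        assert np.isfinite(thr).all()

    def test_monotone_in_threshold(self, rendered):
        air, thr = iso_threshold_slicewise(rendered)
        higher = (rendered < (thr + 10)[:, None, None])
        assert (higher | ~air).all()   # raising thresholds never shrinks air


class TestConnectivity:
    def test_speckles_removed_sphere_kept(self):
        mask = np.zeros((40, 40, 40), bool)
        zz, yy, xx = np.meshgrid(*(np.arange(40),) * 3, indexing="ij")
        sphere = (zz - 30) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 81
        mask |= sphere
        mask[39, 20, 20] = True  # touches top, connect sphere to top face
        mask[31:40, 20, 20] = True
        speck = np.zeros_like(mask)
        speck[5, 5, 5] = speck[10, 30, 8] = True
        out = extract_connected_airways(mask | speck)
        assert not out[5, 5, 5] and not out[10, 30, 8]
        assert (out & sphere).sum() == sphere.sum()

    def test_seed_rule_prefers_top_touching_component(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[25:, 5:10, 5:10] = True      # touches top, smaller
        mask[2:12, 15:28, 15:28] = True   # bigger, not touching top
        out = extract_connected_airways(mask)
        assert out[29, 7, 7]
        assert not out[5, 20, 20]

    def test_no_component_at_seed_keeps_largest(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:10, 5:15, 5:15] = True
        with pytest.warns(UserWarning, match="largest"):
            out = extract_connected_airways(mask)
        assert out.sum() == mask.sum()

    def test_connected_volume_matches_ground_truth(self, foam_phantom):
        # the phantom's airspace plus planted disconnected pockets: the
        # retained volume is the connected airspace alone
        mask = foam_phantom.air_mask.copy()
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in mask.shape),
                                 indexing="ij")
        for cz, cy, cx in [(10, 8, 8), (50, 120, 8), (80, 8, 120)]:
            mask |= ((zz - cz) ** 2 + (yy - cy) ** 2
                     + (xx - cx) ** 2) <= 16
        out = extract_connected_airways(mask)
        assert out.sum() == pytest.approx(foam_phantom.air_mask.sum(),
                                          rel=0.02)


class TestRefine:
    def test_idempotent_on_binary_volume(self):
        vol = np.ones((20, 24, 24))
        vol[5:15, 6:18, 6:18] = 0.0
        mask = vol == 0
        final, v, thr = refine_segmentation(vol, mask, 2.75,
                                            dilation_radius=1,
                                            sharpness_amount=0.0)
        assert np.array_equal(final, mask)

    def test_zero_sharpness_is_plain_second_pass(self, rendered,
                                                 foam_phantom):
        air, _ = iso_threshold_slicewise(
            rendered, cylinder_mask=auto_cylinder_mask(rendered))
        air = extract_connected_airways(air)
        f0, v0, _ = refine_segmentation(rendered, air, 2.75,
                                        sharpness_amount=0.0)
        f1, v1, _ = refine_segmentation(rendered, air, 2.75,
                                        sharpness_amount=1.0)
        assert 0.5 < v0 / v1 < 2.0  # same order; sharpening only refines

    def test_final_mask_inside_dilated_initial(self, rendered):
        air, _ = iso_threshold_slicewise(
            rendered, cylinder_mask=auto_cylinder_mask(rendered))
        air = extract_connected_airways(air)
        final, _, _ = refine_segmentation(rendered, air, 2.75,
                                          dilation_radius=2)
        from skimage.morphology import ball
        dilated = ndimage.binary_dilation(air, structure=ball(2))
        assert not (final & ~dilated).any()

    def test_empty_mask_rejected(self, rendered):
        with pytest.raises(ValueError):
            refine_segmentation(rendered, np.zeros_like(rendered, bool), 2.75)


class TestEndToEnd:
    def test_stagewise_volume_recovery_within_5pct(self, foam_phantom,
                                                   rendered):
        res = segment_airways(rendered, foam_phantom.voxel_size_um,
                              bone_threshold=3 * foam_phantom.mu_tissue)
        est_mm3 = res.volume_cm3 * 1e3
        gt = foam_phantom.air_volume_mm3
        assert abs(est_mm3 - gt) / gt < 0.05
        assert not (res.airway_mask & res.bone_mask).any()

    def test_full_pipeline_volume_recovery_within_10pct(self,
                                                        pipeline_static):
        assert pipeline_static.report["airway_volume_rel_err"] < 0.10
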