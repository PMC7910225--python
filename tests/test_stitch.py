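"""Non-rigid stitching: registration, field recovery, blending, statistics."""

import numpy as np
import pytest
from scipy import ndimage

from mosaictomo.sim import DeformationModel
from mosaictomo.stitch import (DisplacementField, artifact_statistics,
                               blend_mosaic, block_match_field,
                               coarse_pairwise_shift, filter_and_smooth_field,
                               globally_position_tiles)


@pytest.fixture(scope="module")
def textured(small_foam):
    """Mildly smoothed foam: recon-like texture for matching."""
    return ndimage.gaussian_filter(small_foam.volume.astype(float), 0.8)


class TestCoarseShift:
    def test_planted_translation_recovered(self, textured):
        shifted = ndimage.shift(textured, (3, -2, 5), order=1, mode="nearest")
        ps = coarse_pairwise_shift(textured, shifted, (0, 0, 0))
        assert ps.content_shift_vox == pytest.approx([3, -2, 5], abs=0.5)
        assert ps.offset_vox == pytest.approx([-3, 2, -5], abs=0.5)
        assert not ps.low_confidence

    def test_identical_tiles_zero_shift_max_score(self, textured):
        ps = coarse_pairwise_shift(textured, textured, (0, 0, 0))
        assert ps.content_shift_vox == pytest.approx([0, 0, 0], abs=0.1)
        assert ps.score == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_flagged_low_confidence(self, rng):
        a = rng.standard_normal((32, 32, 32))
        b = rng.standard_normal((32, 32, 32))
        with pytest.warns(UserWarning, match="low confidence"):
            ps = coarse_pairwise_shift(a, b, (0, 0, 0))
        assert ps.low_confidence
        assert ps.offset_vox == pytest.approx([0, 0, 0])

    def test_disjoint_tiles_rejected(self, textured):
        with pytest.raises(ValueError, match="overlap"):
            coarse_pairwise_shift(textured, textured, (1000, 0, 0))


def _warp_and_truth(vol, rate, t, seed=7):
    """Warp ``vol`` by a known smooth field; return warped volume and the
    function giving the true local shift at reference points."""
    dm = DeformationModel(rate_vox_per_s=rate, seed=seed,
                          control_spacing_vox=24)
    d = dm.displacement(vol.shape, t)
    coords = np.indices(vol.shape, dtype=float) + d
    warped = ndimage.map_coordinates(vol, coords, order=1, mode="nearest")

    def true_shift(points):
        # match position q solves q + d(q) = p
        q = points.astype(float).copy()
        for _ in range(6):
            dq = np.array([ndimage.map_coordinates(d[a], q.T[:, :, None],
                                                   order=1, mode="nearest")[:, 0]
                           for a in range(3)]).T
            q = points - dq
        return q - points

    return warped, true_shift, d


class TestBlockMatch:
    def test_planted_smooth_field_recovered(self, textured):
        warped, true_shift, d = _warp_and_truth(textured, 1.15, 1.0)
        assert np.abs(d).max() < 4.5
        df = block_match_field(textured, warped, (0, 0, 0),
                               grid_spacing_vox=16, block_radius_vox=8,
                               search_radius_vox=6)
        assert df.valid.sum() >= 10
        exp = true_shift(df.points)
        err = np.linalg.norm(df.shifts[df.valid] - exp[df.valid], axis=1)
        assert err.mean() < 0.5

    def test_zero_deformation_gives_zero_field(self, textured):
        df = block_match_field(textured, textured, (0, 0, 0),
                               grid_spacing_vox=16, block_radius_vox=8,
                               search_radius_vox=4)
        assert np.abs(df.shifts[df.valid]).max() < 0.5

    def test_block_larger_than_overlap_all_invalid(self, textured):
        small = textured[:20, :20, :20]
        with pytest.warns(UserWarning, match="no valid"):
            df = block_match_field(small, small, (0, 0, 0),
                                   grid_spacing_vox=16,
                                   block_radius_vox=30,
                                   search_radius_vox=4)
        assert not df.valid.any()


class TestFilterSmooth:
    def _field(self, shifts, valid=None):
        n = len(shifts)
        pts = np.array([[0, 0, 16 * i] for i in range(n)], dtype=float)
        return DisplacementField(points=pts,
                                 shifts=np.asarray(shifts, dtype=float),
                                 valid=np.ones(n, bool) if valid is None
                                 else np.asarray(valid),
                                 scores=np.ones(n),
                                 rigid_offset=np.zeros(3))

    def test_planted_outlier_removed_and_interpolated(self):
        shifts = [[1, 0, 0]] * 7
        shifts[3] = [30, 0, 0]
        df = filter_and_smooth_field(self._field(shifts))
        assert df.meta["n_rejected"] == 1
        assert df.shifts[3] == pytest.approx([1, 0, 0], abs=1.0)

    def test_constant_field_unchanged(self):
        df = filter_and_smooth_field(self._field([[2, -1, 3]] * 6))
        assert df.shifts == pytest.approx(np.tile([2, -1, 3], (6, 1)))

    def test_alternating_spikes_smoothed(self):
        shifts = [[(-1) ** i * 3.0, 0, 0] for i in range(10)]
        df = filter_and_smooth_field(self._field(shifts))
        grad = np.abs(np.diff(df.shifts[:, 0])) / 16.0
        assert grad.max() < 0.1

    def test_all_invalid_returns_identity(self):
        with pytest.warns(UserWarning, match="identity"):
            df = filter_and_smooth_field(
                self._field([[1, 1, 1]] * 4, valid=[False] * 4))
        assert not df.valid.any()
        assert np.all(df.shifts == 0)
        assert df.meta["identity"]


class TestGlobalPositions:
    def test_consistent_cycle_reproduced_exactly(self):
        nominal = np.array([[0, 0, 0], [0, 0, 50], [0, 50, 0], [0, 50, 50]],
                           dtype=float)
        pairwise = {}
        for a, b in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            pairwise[(a, b)] = (nominal[b] - nominal[a] + 0.5, 1.0)
        origins = globally_position_tiles(4, pairwise, nominal)
        for (a, b), (off, _) in pairwise.items():
            assert origins[b] - origins[a] == pytest.approx(off, abs=1e-8)

    def test_inconsistent_low_confidence_edge_absorbs_residual(self):
        nominal = np.array([[0, 0, 0], [0, 0, 50], [0, 50, 0]], dtype=float)
        pairwise = {
            (0, 1): (np.array([0, 0, 50.0]), 1.0),
            (0, 2): (np.array([0, 50.0, 0]), 1.0),
            (1, 2): (np.array([0, 50.0, -50.0]) + [0, 6.0, 0], 0.01),
        }
        origins = globally_position_tiles(3, pairwise, nominal)
        r01 = origins[1] - origins[0] - pairwise[(0, 1)][0]
        r12 = origins[2] - origins[1] - pairwise[(1, 2)][0]
        assert np.linalg.norm(r01) < 0.5
        assert np.linalg.norm(r12) > 4.0

    def test_single_tile_stays_nominal(self):
        origins = globally_position_tiles(1, {}, np.array([[1.0, 2.0, 3.0]]))
        assert origins[0] == pytest.approx([1, 2, 3])

    def test_disconnected_components_warn(self):
        nominal = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="components"):
            globally_position_tiles(3, {(0, 1): (np.zeros(3), 1.0)}, nominal)


class TestBlend:
    def test_identical_constant_tiles_fuse_to_constant(self):
        tiles = [np.full((16, 16, 16), 7.0), np.full((16, 16, 16), 7.0)]
        origins = np.array([[0, 0, 0], [0, 0, 8]], dtype=float)
        res = blend_mosaic(tiles, origins)
        covered = res.provenance != 255
        assert res.fused[covered] == pytest.approx(7.0)
        assert np.all(res.std_map == 0)
        assert res.overlap_mask.any()

    def test_two_constant_tiles_differing_by_d(self):
        tiles = [np.full((16, 16, 16), 10.0), np.full((16, 16, 16), 14.0)]
        origins = np.array([[0, 0, 0], [0, 0, 8]], dtype=float)
        res = blend_mosaic(tiles, origins)
        # population std of {10, 14} is d/2 = 2 in the overlap
        assert res.std_map[res.overlap_mask] == pytest.approx(2.0)

    def test_provenance_covers_every_fused_voxel(self):
        tiles = [np.ones((12, 12, 12)), np.ones((12, 12, 12))]
        origins = np.array([[0, 0, 0], [0, 0, 6]], dtype=float)
        res = blend_mosaic(tiles, origins)
        assert np.all(res.provenance != 255)

    def test_warp_reduces_ground_truth_error(self, pipeline_deformed):
        # full-pipeline ablation on the deformed 2x1x2 mosaic
        from mosaictomo.config import desk_scale_config
        from mosaictomo.pipeline import stitch_tiles
        cfg = desk_scale_config(seed=1, deformed=True)
        res = pipeline_deformed
        thr = 0.25 * res.phantom.mu_tissue
        rigid = stitch_tiles(res.tiles, cfg, non_rigid=False,
                             std_threshold=thr)
        nonrigid = res.stitched
        ov_nr = nonrigid.std_map[nonrigid.overlap_mask]
        ov_r = rigid.std_map[rigid.overlap_mask]
        assert np.sqrt((ov_nr ** 2).mean()) < np.sqrt((ov_r ** 2).mean())


class TestArtifactStatistics:
    def test_all_zero_std(self):
        frac, per_slice, mx = artifact_statistics(np.zeros((4, 8, 8)), 1.0)
        assert frac == 0.0 and mx == 0.0

    def test_planted_fraction_counted(self, rng):
        std = np.zeros((10, 20, 20))
        hot = rng.choice(std.size, size=int(0.01 * std.size), replace=False)
        std.ravel()[hot] = 5.0
        frac, per_slice, mx = artifact_statistics(std, 1.0)
        assert frac == pytest.approx(0.01)
        assert mx >= frac

    def test_deformed_worse_than_static(self, pipeline_static,
                                        pipeline_deformed):
        assert pipeline_deformed.report["artifact_fraction"] > \
            pipeline_static.report["artifact_fraction"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            artifact_statistics(np.zeros((2, 2, 2)), 0.0)
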