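"""Filtered back-projection, extended FOV, centre finding."""

import numpy as np
import pytest

from mosaictomo.recon import (fbp_slice, find_center, interpolate_centers,
                              reconstruct_extended_fov)
from mosaictomo.sim import project_parallel, scan_angles

VOX = 2.75
MU0 = 60.0


def disc_volume(n=96, radius=30.0, mu0=MU0):
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rr = np.sqrt((yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2)
    vol = np.clip(radius + 0.5 - rr, 0, 1)[None] * mu0
    return vol, rr


def blobby_volume(n=96, seed=6):
    """Disc with internal structure; asymmetric enough to test geometry."""
    vol, rr = disc_volume(n)
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for _ in range(6):
        cy, cx = rng.uniform(n * 0.3, n * 0.7, 2)
        r = rng.uniform(4, 9)
        blob = np.clip(r + 0.5 - np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2),
                       0, 1)
        vol[0] *= (1 - 0.8 * blob)
    return vol, rr


class TestFbpSlice:
    def test_uniform_disc_recovery(self):
        vol, rr = disc_volume()
        angles = np.arange(0, 360, 1.0)
        sino = project_parallel(vol, angles, 63.5, 128, VOX)
        rec = fbp_slice(sino[:, 0, :], angles, pixel_size_um=VOX)
        o = (128 - 96) // 2
        rec = rec[o:o + 96, o:o + 96]
        inside = rr <= 28
        assert rec[inside].mean() / MU0 == pytest.approx(1.0, abs=0.05)
        disc = rr <= 30
        rmse = np.sqrt(((rec - vol[0])[disc] ** 2).mean())
        assert rmse < 0.05 * MU0

    def test_zero_sinogram_reconstructs_to_zero(self):
        rec = fbp_slice(np.zeros((90, 64)), np.arange(0, 180, 2.0))
        assert np.abs(rec).max() < 1e-12

    def test_shift_equivariance(self):
        # translating the rotation axis on the detector by s voxels and
        # telling the reconstructor about it must leave the slice unchanged
        vol, _ = blobby_volume()
        angles = np.arange(0, 180, 1.0)
        s = 6
        sino_a = project_parallel(vol, angles, 63.5, 128, VOX)[:, 0, :]
        sino_b = project_parallel(vol, angles, 63.5 + s, 128, VOX)[:, 0, :]
        rec_a = fbp_slice(sino_a, angles, center_px=63.5)
        rec_b = fbp_slice(sino_b, angles, center_px=63.5 + s)
        gy, gx = np.meshgrid(np.arange(128) - 63.5, np.arange(128) - 63.5,
                             indexing="ij")
        obj = gy ** 2 + gx ** 2 <= 32 ** 2
        diff = np.abs(rec_a - rec_b)[obj]
        assert diff.max() < 0.01 * np.ptp(rec_a[obj])

    def test_linearity_in_sinogram(self, rng):
        sino_a = rng.random((45, 40))
        sino_b = rng.random((45, 40))
        angles = np.arange(0, 180, 4.0)
        rec = fbp_slice(2 * sino_a + sino_b, angles)
        assert rec == pytest.approx(2 * fbp_slice(sino_a, angles)
                                    + fbp_slice(sino_b, angles), abs=1e-9)

    def test_full_turn_matches_half_turn(self):
        vol, _ = blobby_volume()
        a180 = np.arange(0, 180, 1.0)
        a360 = np.arange(0, 360, 1.0)
        r180 = fbp_slice(project_parallel(vol, a180, 63.5, 128, VOX)[:, 0],
                         a180, pixel_size_um=VOX)
        r360 = fbp_slice(project_parallel(vol, a360, 63.5, 128, VOX)[:, 0],
                         a360, pixel_size_um=VOX)
        inner = slice(24, 104)
        assert r360[inner, inner] == pytest.approx(r180[inner, inner],
                                                   abs=0.02 * MU0)

    def test_limited_coverage_warns(self):
        with pytest.warns(UserWarning, match="coverage"):
            fbp_slice(np.ones((30, 16)), np.linspace(0, 90, 30))

    def test_mass_conservation_smooth_phantom(self):
        n = 96
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr2 = (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2
        vol = (MU0 * np.exp(-rr2 / (2 * 12.0 ** 2)))[None]
        angles = np.arange(0, 180, 1.0)
        sino = project_parallel(vol, angles, 63.5, 128, VOX)
        rec = fbp_slice(sino[:, 0, :], angles, pixel_size_um=VOX)
        gy, gx = np.meshgrid(np.arange(128) - 63.5, np.arange(128) - 63.5,
                             indexing="ij")
        interior = gy ** 2 + gx ** 2 <= 40 ** 2
        assert rec[interior].sum() == pytest.approx(vol[0].sum(), rel=0.02)


@pytest.fixture(scope="module")
def offset_scan():
    vol, rr = blobby_volume()
    angles = scan_angles(400, 0.04565)
    sino = project_parallel(vol, angles, 8.0, 66, VOX)
    return vol, rr, sino


class TestExtendedFov:

    def test_matches_full_fov_oracle(self, offset_scan):
        vol, rr, sino = offset_scan
        # oracle: direct 180-degree full-detector reconstruction
        a_or = np.arange(0, 180, 0.9)
        sino_or = project_parallel(vol, a_or, 63.5, 128, VOX)
        rec_or = fbp_slice(sino_or[:, 0, :], a_or, pixel_size_um=VOX)
        o = (128 - 96) // 2
        rec_or = rec_or[o:o + 96, o:o + 96]
        rec = reconstruct_extended_fov(sino, 8.0, eps_deg=0.04565,
                                       pixel_size_um=VOX)
        D = rec.shape[-1]
        oe = (D - 96) // 2
        rec = rec[0, oe:oe + 96, oe:oe + 96]
        disc = rr <= 30
        rmse_or = np.sqrt(((rec_or - vol[0])[disc] ** 2).mean())
        rmse_ext = np.sqrt(((rec - vol[0])[disc] ** 2).mean())
        assert rmse_ext < 2.0 * rmse_or

    def test_ignoring_angular_offset_degrades(self):
        # the 0.04565-degree complementary-pair offset displaces structure
        # by ~eps*r at radius r; its neglect is only resolvable at radii of
        # a hundred-plus pixels, hence the wider phantom here
        from mosaictomo.phantom import make_foam_phantom
        n, R, off = 256, 118, 8.0
        ph = make_foam_phantom((1, n, n), target_air_fraction=0.5, seed=0,
                               mu_tissue=2000.0, wall_thickness_um=8.0)
        angles = scan_angles(800, 0.04565)
        sino = project_parallel(ph.volume, angles, off, int(off + R + 8),
                                VOX)

        def rmse(eps):
            rec = reconstruct_extended_fov(sino, off, eps_deg=eps,
                                           pixel_size_um=VOX)
            D = rec.shape[-1]
            ov = (n - D) // 2
            gt = ph.volume[0][ov:ov + D, ov:ov + D]
            gy, gx = np.meshgrid(np.arange(D) - (D - 1) / 2,
                                 np.arange(D) - (D - 1) / 2, indexing="ij")
            m = gy ** 2 + gx ** 2 <= (R - 6) ** 2
            return np.sqrt(((rec[0] - gt)[m] ** 2).mean())

        assert rmse(0.0) > rmse(0.04565)

    def test_output_diameter_geometry_limits(self):
        sino = np.zeros((8, 1, 40))
        angles = np.arange(0, 360, 45.0)
        rec_edge = reconstruct_extended_fov(sino, 0.0, angles_deg=angles)
        assert rec_edge.shape[-1] == 80     # axis at the edge: doubled FOV
        rec_mid = reconstruct_extended_fov(sino, 19.5, angles_deg=angles)
        assert abs(rec_mid.shape[-1] - 40) <= 1   # mid-axis: standard FOV

    def test_axis_near_right_edge_mirrors(self, offset_scan):
        # mirrored detector data with the mirrored centre must reconstruct
        # the mirrored slice
        vol, rr, sino = offset_scan
        rec_l = reconstruct_extended_fov(sino, 8.0, eps_deg=0.04565,
                                         pixel_size_um=VOX)
        rec_r = reconstruct_extended_fov(sino[:, :, ::-1], 66 - 1 - 8.0,
                                         eps_deg=0.04565, pixel_size_um=VOX)
        assert rec_r.shape == rec_l.shape
        assert rec_r[:, :, ::-1] == pytest.approx(rec_l, abs=1e-9)

    def test_unspecified_eps_warns(self):
        with pytest.warns(UserWarning, match="eps"):
            reconstruct_extended_fov(np.zeros((8, 1, 16)), 2.0)


@pytest.fixture(scope="module")
def foam_sino():
    from mosaictomo.phantom import make_foam_phantom
    ph = make_foam_phantom((8, 96, 96), target_air_fraction=0.5,
                           seed=9, mu_tissue=2000.0)
    angles = np.arange(360) * 0.5
    sino = project_parallel(ph.volume, angles, 100.0, 128, VOX)
    return sino, angles


class TestFindCenter:

    def test_planted_center_recovered(self, foam_sino):
        sino, angles = foam_sino
        c, report = find_center(sino, angles, (95.0, 105.0), 0.5)
        assert abs(c - 100.0) <= 0.5
        assert not report["at_edge"]

    def test_score_curve_symmetric_for_disc(self):
        vol, _ = disc_volume()
        angles = np.arange(360) * 0.5
        sino = project_parallel(vol, angles, 64.0, 128, VOX)
        _, report = find_center(sino[:, 0, :], angles, (60.0, 68.0), 1.0)
        s = report["scores"]
        assert s == pytest.approx(s[::-1], rel=0.2, abs=0.1 * np.ptp(s) + 1e-9)

    def test_range_excluding_center_flags_edge(self, foam_sino):
        sino, angles = foam_sino
        with pytest.warns(UserWarning, match="edge"):
            c, report = find_center(sino, angles, (90.0, 96.0), 0.5)
        assert report["at_edge"]
        assert c in (90.0, 96.0)

    def test_flat_curve_returns_midpoint(self):
        sino = np.zeros((90, 32))
        angles = np.arange(0, 180, 2.0)
        with pytest.warns(UserWarning, match="flat"):
            c, report = find_center(sino, angles, (10.0, 20.0), 1.0)
        assert c == 15.0
        assert report["flat"]


class TestInterpolateCenters:
    def test_linear_progression(self):
        assert interpolate_centers(100.0, 106.0, 7) == \
            pytest.approx([100, 101, 102, 103, 104, 105, 106])

    def test_constant_when_equal(self):
        assert interpolate_centers(50.0, 50.0, 5) == \
            pytest.approx([50.0] * 5)

    def test_two_layers_are_endpoints(self):
        assert interpolate_centers(10.0, 20.0, 2) == pytest.approx([10, 20])

    def test_invalid_layer_count(self):
        with pytest.raises(ValueError):
            interpolate_centers(0.0, 1.0, 0)
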