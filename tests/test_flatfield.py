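"""Flat-field correction: static, PCA basis, dynamic weights, ring metrics."""

import numpy as np
import pytest

from mosaictomo.flatfield import (FlatFieldModel, background_margin_mask,
                                  correct_dynamic, correct_static,
                                  fit_flat_basis, ring_metric, stripe_metric)
from mosaictomo.sim import IlluminationModel

SHAPE = (32, 48)


def _model_from(illum, n_flats=300, K=5, seed=2):
    rng = np.random.default_rng(seed)
    flats = illum.sample_flats(n_flats, rng)
    darks = illum.sample_darks(50, rng)
    return fit_flat_basis(flats, darks.mean(axis=0), K=K)


class TestStatic:
    @pytest.fixture()
    def model(self):
        dark = np.full(SHAPE, 100.0)
        flat = 5000.0 * (1 + 0.1 * np.random.default_rng(0).random(SHAPE))
        return FlatFieldModel(dark_mean=dark, flat_mean=flat,
                              components=np.zeros((0,) + SHAPE),
                              eigenvalues=np.zeros(0))

    def test_flat_maps_to_one(self, model):
        raw = model.flat_mean + model.dark_mean
        assert correct_static(raw, model) == pytest.approx(np.ones(SHAPE))

    def test_dark_maps_to_zero(self, model):
        assert correct_static(model.dark_mean, model) == \
            pytest.approx(np.zeros(SHAPE))

    def test_linearity_halfway(self, model):
        raw = model.dark_mean + 0.5 * model.flat_mean
        assert correct_static(raw, model) == pytest.approx(0.5 * np.ones(SHAPE))

    def test_nonpositive_denominator_rejected(self, model):
        bad = FlatFieldModel(dark_mean=model.dark_mean,
                             flat_mean=model.flat_mean - 1e5,
                             components=model.components,
                             eigenvalues=model.eigenvalues)
        with pytest.raises(ValueError, match="pixels"):
            correct_static(model.flat_mean, bad)


class TestFitBasis:
    def test_identical_flats_have_zero_eigenvalues(self):
        flats = np.tile(np.random.default_rng(0).random(SHAPE) * 100 + 500,
                        (20, 1, 1))
        model = fit_flat_basis(flats, np.zeros(SHAPE), K=3)
        assert model.eigenvalues == pytest.approx(np.zeros(3), abs=1e-6)
        assert model.flat_mean == pytest.approx(flats[0])

    def test_rank_one_drift_recovered(self, rng):
        base = 1000 + 100 * rng.random(SHAPE)
        u = rng.standard_normal(SHAPE)
        u -= u.mean()
        coeffs = rng.standard_normal(40)
        flats = base[None] + coeffs[:, None, None] * u[None]
        model = fit_flat_basis(flats, np.zeros(SHAPE), K=2)
        c = np.abs(np.vdot(model.components[0], u / np.linalg.norm(u)))
        assert c == pytest.approx(1.0, abs=1e-8)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-6)

    def test_planted_subspace_recovered_within_5_degrees(self):
        illum = IlluminationModel.make(SHAPE, n_components=3, seed=1)
        model = _model_from(illum, K=3)
        U = illum.components.reshape(3, -1)
        V = model.components.reshape(3, -1)
        qu, _ = np.linalg.qr(U.T)
        qv, _ = np.linalg.qr(V.T)
        svals = np.clip(np.linalg.svd(qu.T @ qv, compute_uv=False), -1, 1)
        angles = np.degrees(np.arccos(svals))
        assert np.all(angles < 5.0)

    def test_components_orthonormal_and_sorted(self):
        illum = IlluminationModel.make(SHAPE, n_components=3, seed=1)
        model = _model_from(illum, K=4)
        V = model.components.reshape(4, -1)
        assert V @ V.T == pytest.approx(np.eye(4), abs=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)

    def test_subspace_error_nonincreasing_in_K(self):
        illum = IlluminationModel.make(SHAPE, n_components=3, seed=1)
        rng = np.random.default_rng(2)
        flats = illum.sample_flats(60, rng)
        dark = np.full(SHAPE, illum.dark_mean)
        errs = []
        X = (flats - dark).reshape(60, -1)
        for K in (1, 2, 3, 5, 8):
            model = fit_flat_basis(flats, dark, K=K)
            Xc = X - model.flat_mean.ravel()
            V = model.components.reshape(K, -1)
            resid = Xc - (Xc @ V.T) @ V
            errs.append(np.linalg.norm(resid))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="K"):
            fit_flat_basis(np.ones((5,) + SHAPE), np.zeros(SHAPE), K=5)


class TestDynamic:
    def test_planted_weight_recovered_exactly(self):
        illum = IlluminationModel.make(SHAPE, n_components=1, seed=3)
        u = illum.components[0]
        u_hat = u / np.linalg.norm(u)
        model = FlatFieldModel(dark_mean=np.full(SHAPE, 100.0),
                               flat_mean=illum.mean_flat,
                               components=u_hat[None],
                               eigenvalues=np.array([1.0]))
        raw = 100.0 + illum.mean_flat + 0.7 * u
        corrected, w = correct_dynamic(raw, model, np.ones(SHAPE, bool))
        assert w[0] == pytest.approx(0.7 * np.linalg.norm(u), abs=1e-6)
        assert corrected == pytest.approx(np.ones(SHAPE), abs=1e-9)

    def test_k_zero_equals_static(self):
        dark = np.full(SHAPE, 100.0)
        flat = np.full(SHAPE, 4000.0)
        model = FlatFieldModel(dark_mean=dark, flat_mean=flat,
                               components=np.zeros((0,) + SHAPE),
                               eigenvalues=np.zeros(0))
        raw = dark + 0.5 * flat
        d, w = correct_dynamic(raw, model, np.ones(SHAPE, bool))
        assert w.size == 0
        assert d == pytest.approx(correct_static(raw, model))

    def test_empty_background_rejected(self):
        model = FlatFieldModel(dark_mean=np.zeros(SHAPE),
                               flat_mean=np.ones(SHAPE),
                               components=np.ones((1,) + SHAPE),
                               eigenvalues=np.ones(1))
        with pytest.raises(ValueError, match="background"):
            correct_dynamic(np.ones(SHAPE), model, np.zeros(SHAPE, bool))

    def test_margin_mask_shape(self):
        m = background_margin_mask((10, 30), margin_cols=5)
        assert m[:, :5].all() and m[:, -5:].all()
        assert not m[:, 5:-5].any()


class TestMetrics:
    def test_ring_metric_zero_for_constant(self):
        assert ring_metric(np.full((64, 64), 3.0)) == pytest.approx(0.0)

    def test_ring_metric_monotone_in_ring_amplitude(self):
        n = 96
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr = np.sqrt((yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2)
        ring = np.exp(-((rr - 20) ** 2) / 2.0)
        scores = [ring_metric(a * ring) for a in (0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_ring_metric_small_for_smooth_symmetric_slice(self):
        n = 96
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr = np.sqrt((yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2)
        smooth = 1.0 / (1.0 + (rr / 20) ** 2)
        ring = 5.0 * np.exp(-((rr - 20) ** 2) / 2.0)
        assert ring_metric(smooth) < 0.1 * ring_metric(smooth + ring)

    def test_stripe_metric_detects_fixed_pattern(self, rng):
        trans = np.full((120, 64), 0.5)
        stripes = 0.02 * rng.standard_normal(64)
        assert stripe_metric(trans * (1 + stripes)) > \
            5 * stripe_metric(trans)
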