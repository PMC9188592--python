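"""Velocity-field comparison: down-sampling, smoothing, agreement stats."""

import numpy as np
import pytest

from coaflow.compare import (VectorField, bland_altman, correlation,
                             downsample, smooth_field, smoothn)


def _smooth_field_3d(shape=(24, 20, 16), ncomp=3, freq=0.25):
    ax = [np.arange(n, dtype=float) for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    comps = [np.sin(freq * X) * np.cos(freq * Y),
             np.cos(freq * Y) * np.sin(freq * Z),
             np.sin(freq * (X + Z))][:ncomp]
    return VectorField(origin=np.zeros(3), spacing=np.ones(3),
                       data=np.stack(comps, axis=-1))


class TestDownsample:
    def test_constant_field_reproduced(self):
        fld = VectorField([0, 0, 0], [1, 1, 1], np.full((8, 8, 8, 3), 1.7))
        co = downsample(fld, [0.5, 0.5, 0.5], [2, 2, 2], (3, 3, 3))
        assert np.allclose(co.data, 1.7)

    def test_linear_field_exact(self):
        ax = [np.arange(n, dtype=float) for n in (10, 9, 8)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        data = np.stack([1 + 0.2 * X, 0.3 * Y - 0.1 * Z, 0.5 * Z], axis=-1)
        fld = VectorField([0, 0, 0], [1, 1, 1], data)
        co = downsample(fld, [1.25, 1.25, 1.25], [2.5, 2.0, 1.5], (4, 4, 4))
        Xc, Yc, Zc = np.meshgrid(*[1.25 + s * np.arange(4)
                                   for s in (2.5, 2.0, 1.5)], indexing="ij")
        expected = np.stack([1 + 0.2 * Xc, 0.3 * Yc - 0.1 * Zc, 0.5 * Zc], -1)
        assert np.allclose(co.data, expected, atol=1e-12)

    def test_probe_points_vs_manual_trilinear(self):
        fld = _smooth_field_3d()
        co = downsample(fld, [3.2, 2.1, 1.7], [1, 1, 1], (2, 2, 2))
        # manual trilinear oracle at one probe
        x, y, z = 3.2, 2.1, 1.7
        i, j, k = int(x), int(y), int(z)
        fx, fy, fz = x - i, y - j, z - k
        c = fld.data
        manual = 0.0
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    manual += wx * wy * wz * c[i + di, j + dj, k + dk, 0]
        assert co.data[0, 0, 0, 0] == pytest.approx(manual, abs=1e-12)

    def test_out_of_bounds_rejected(self):
        fld = _smooth_field_3d((8, 8, 8))
        with pytest.raises(ValueError):
            downsample(fld, [-1, 0, 0], [2, 2, 2], (3, 3, 3))

    def test_mask_propagates_conservatively(self):
        fld = _smooth_field_3d((8, 8, 8))
        fld.mask[4, 4, 4] = False
        co = downsample(fld, [3.5, 3.5, 3.5], [1, 1, 1], (2, 2, 2))
        assert not co.mask[0, 0, 0]  # voxel straddling the invalid cell

    def test_downsampled_self_comparison_is_exact_zero(self):
        fld = _smooth_field_3d()
        co = downsample(fld, [1.3, 1.3, 1.3], [2.5, 2.5, 2.5], (6, 5, 4))
        rep = bland_altman(co, co)
        assert rep.bias == 0.0 and rep.loa_half_width == 0.0


class TestSmoothing:
    def test_constant_field_unchanged(self):
        z, _ = smoothn(np.full((20, 20), 3.0))
        assert np.allclose(z, 3.0, atol=1e-8)

    def test_noiseless_smooth_field_preserved(self):
        fld = _smooth_field_3d((20, 18, 14))
        out = smooth_field(fld)
        rms = np.sqrt(np.mean((out.data - fld.data) ** 2))
        scale = np.sqrt(np.mean(fld.data**2))
        assert rms / scale < 0.01

    def test_injected_outlier_replaced(self):
        fld = _smooth_field_3d((16, 16, 12), ncomp=3)
        i = (8, 8, 6)
        clean = fld.data[i + (0,)]
        fld.data[i + (0,)] += 10.0 * max(abs(clean), 0.5)
        out = smooth_field(fld, robust=True)
        nb = fld.data[6:11, 6:11, 4:9, 0]
        assert abs(out.data[i + (0,)] - clean) < 3.0 * nb.std()

    def test_noise_reduction_at_moderate_snr(self):
        rng = np.random.default_rng(10)
        fld = _smooth_field_3d((20, 18, 14))
        sigma = np.sqrt(np.mean(fld.data**2)) / 5.0  # SNR = 5
        noisy = VectorField(fld.origin, fld.spacing,
                            fld.data + rng.normal(0, sigma, fld.data.shape))
        out = smooth_field(noisy)
        rms_before = np.sqrt(np.mean((noisy.data - fld.data) ** 2))
        rms_after = np.sqrt(np.mean((out.data - fld.data) ** 2))
        assert rms_after < rms_before

    def test_all_invalid_rejected(self):
        fld = _smooth_field_3d((8, 8, 8))
        fld.mask[:] = False
        with pytest.raises(ValueError):
            smooth_field(fld)


class TestAgreement:
    def test_identical_fields(self):
        fld = _smooth_field_3d()
        rep = bland_altman(fld, fld)
        assert rep.bias == 0.0 and rep.loa_half_width == 0.0

    def test_constant_offset(self):
        a = _smooth_field_3d((10, 10, 8), ncomp=1)
        b = VectorField(a.origin, a.spacing, a.data + 0.25)
        rep = bland_altman(a, b, mode="component")
        assert rep.bias == pytest.approx(-0.25)
        assert rep.loa_half_width == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_bias_and_loa(self):
        # construct a pair whose differences are N(-0.05, 0.098):
        # expect bias ~ -0.05 and LoA ~ 1.96*0.098 = 0.192
        rng = np.random.default_rng(12)
        base = np.abs(rng.normal(1.0, 0.3, (40, 40, 20, 1)))
        diff = rng.normal(-0.05, 0.098, base.shape)
        a = VectorField([0, 0, 0], [1, 1, 1], base)
        b = VectorField([0, 0, 0], [1, 1, 1], base - diff)
        rep = bland_altman(a, b, mode="component")
        assert rep.bias == pytest.approx(-0.05, abs=0.003)
        assert rep.loa_half_width == pytest.approx(0.192, abs=0.005)

    def test_perfect_linear_relation(self):
        a = _smooth_field_3d((10, 10, 8), ncomp=1)
        b = VectorField(a.origin, a.spacing, 2.0 * a.data + 1.0)
        rep = correlation(a, b, mode="component")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = _smooth_field_3d((10, 10, 8), ncomp=1)
        b = VectorField(a.origin, a.spacing, -a.data)
        assert correlation(a, b, mode="component").pearson_r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        a = VectorField([0, 0], [1, 1], rng.normal(size=(30, 30, 1)))
        b = VectorField([0, 0], [1, 1], rng.normal(size=(30, 30, 1)))
        r0 = correlation(a, b, mode="component").pearson_r
        b2 = VectorField([0, 0], [1, 1], 3.0 * b.data - 0.7)
        assert correlation(a, b2, mode="component").pearson_r \
            == pytest.approx(r0, abs=1e-12)

    def test_random_pair_vs_textbook_formula(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 12, 1))
        y = 0.5 * x + rng.normal(scale=0.5, size=x.shape)
        a = VectorField([0, 0], [1, 1], x)
        b = VectorField([0, 0], [1, 1], y)
        xm, ym = x.ravel() - x.mean(), y.ravel() - y.mean()
        r_hand = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert correlation(a, b, mode="component").pearson_r \
            == pytest.approx(r_hand, abs=1e-12)

    def test_r_squared_is_r_squared(self):
        rng = np.random.default_rng(15)
        a = VectorField([0, 0], [1, 1], rng.normal(size=(20, 20, 1)))
        b = VectorField([0, 0], [1, 1], rng.normal(size=(20, 20, 1)))
        rep = correlation(a, b, mode="component")
        assert rep.r_squared == pytest.approx(rep.pearson_r**2, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = _smooth_field_3d((8, 8, 8))
        b = _smooth_field_3d((9, 8, 8))
        with pytest.raises(ValueError):
            bland_altman(a, b)

    def test_zero_variance_rejected(self):
        a = VectorField([0, 0], [1, 1], np.ones((8, 8, 1)))
        with pytest.raises(ValueError):
            correlation(a, a, mode="component")
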