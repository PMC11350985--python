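"""Gabor kernels, DC removal, parameter estimation, feature extraction."""

import numpy as np
import pytest

from retinograde.gabor import (
    BankConfig,
    GaborParams,
    estimate_local_params,
    extract_features,
    filter_image,
    gabor_kernel,
    remove_dc,
)


def brute_force_kernel(p: GaborParams):
    """Direct per-pixel evaluation of the envelope/carrier formulas."""
    n = 2 * p.k + 1
    real = np.empty((n, n))
    imag = np.empty((n, n))
    th = np.deg2rad(p.theta)
    for iy in range(-p.k, p.k + 1):
        for ix in range(-p.k, p.k + 1):
            g = np.exp(-(ix**2 + iy**2) / (2 * p.sigma**2)) / (2 * np.pi * p.sigma**2)
            phase = 2 * np.pi * p.mu * (ix * np.cos(th) + iy * np.sin(th))
            real[iy + p.k, ix + p.k] = g * np.cos(phase)
            imag[iy + p.k, ix + p.k] = g * np.sin(phase)
    return real, imag


class TestKernel:
    def test_mu_zero_is_pure_gaussian(self):
        kern = gabor_kernel(GaborParams(sigma=2.0, mu=0.0, theta=45.0, k=5))
        assert np.allclose(kern.imag, 0.0)
        assert kern.real[5, 5] == pytest.approx(1 / (2 * np.pi * 4.0))

    def test_center_entry(self):
        p = GaborParams(sigma=3.0, mu=0.2, theta=30.0, k=4)
        kern = gabor_kernel(p)
        assert kern.real[4, 4] == pytest.approx(1 / (2 * np.pi * 9.0))
        assert kern.imag[4, 4] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "p",
        [
            GaborParams(sigma=2.0, mu=0.25, theta=90.0, k=7),
            GaborParams(sigma=1.5, mu=0.1, theta=30.0, k=5),
            GaborParams(sigma=4.0, mu=0.05, theta=157.5, k=7),
        ],
    )
    def test_matches_brute_force(self, p):
        kern = gabor_kernel(p)
        real, imag = brute_force_kernel(p)
        assert np.max(np.abs(kern.real - real)) < 1e-12
        assert np.max(np.abs(kern.imag - imag)) < 1e-12

    def test_invalid_params_rejected(self):
        for kwargs in (
            dict(sigma=0.0, mu=0.1, theta=0.0, k=3),
            dict(sigma=1.0, mu=-0.1, theta=0.0, k=3),
            dict(sigma=1.0, mu=0.1, theta=180.0, k=3),
            dict(sigma=1.0, mu=0.1, theta=0.0, k=0),
        ):
            with pytest.raises(ValueError):
                GaborParams(**kwargs)


class TestRemoveDC:
    def test_sum_is_zero(self):
        kern = remove_dc(gabor_kernel(GaborParams(2.0, 0.1, 60.0, 6)))
        assert abs(kern.real.sum()) < 1e-10
        assert abs(kern.imag.sum()) < 1e-10

    def test_double_removal_rejected(self):
        kern = remove_dc(gabor_kernel(GaborParams(2.0, 0.1, 60.0, 6)))
        with pytest.raises(ValueError):
            remove_dc(kern)

    def test_constant_image_zero_response(self):
        kern = remove_dc(gabor_kernel(GaborParams(2.0, 0.15, 45.0, 5)))
        out = filter_image(np.full((32, 32), 100.0), kern)
        assert np.max(np.abs(out)) < 1e-9

    def test_max_of_gaussian_decreases(self):
        raw = gabor_kernel(GaborParams(2.0, 0.0, 0.0, 5))
        dc = remove_dc(raw)
        assert dc.real.max() < raw.real.max()


class TestEstimateParams:
    def grating(self, deg, freq, size=64, contrast=40.0):
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        th = np.deg2rad(deg)
        return 100 + contrast * np.cos(2 * np.pi * freq * (xx * np.cos(th) + yy * np.sin(th)))

    def test_recovers_grating_orientation_and_frequency(self):
        p, fallback = estimate_local_params(self.grating(30.0, 0.1))
        assert not fallback
        assert abs((p.theta - 30.0 + 90) % 180 - 90) < 5.0
        assert p.mu == pytest.approx(0.1, rel=0.2)

    def test_rotated_grating_shifts_90(self):
        p1, _ = estimate_local_params(self.grating(30.0, 0.1))
        p2, _ = estimate_local_params(self.grating(120.0, 0.1))
        diff = (p2.theta - p1.theta) % 180
        assert abs(diff - 90.0) < 10.0

    def test_constant_tile_falls_back(self):
        cfg = BankConfig()
        p, fallback = estimate_local_params(np.full((32, 32), 9.0), cfg)
        assert fallback
        assert p == cfg.default_params

    def test_small_tile_rejected(self):
        with pytest.raises(ValueError):
            estimate_local_params(np.zeros((8, 8)))


class TestExtractFeatures:
    BANK = BankConfig(thetas=(0.0, 90.0), mus=(0.1,), tiles=2)

    def test_constant_image_all_bank_features_zero(self):
        f = extract_features(np.full((64, 64), 55.0), bank=self.BANK)
        bank = f[[c for c in f.index if c.startswith("bank_") and not c.endswith("fallback")]]
        assert np.allclose(bank.values, 0.0, atol=1e-9)

    def test_deterministic(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        f1 = extract_features(img, bank=self.BANK)
        f2 = extract_features(img, bank=self.BANK)
        assert f1.equals(f2)

    def test_illumination_invariance(self, rng):
        img = rng.uniform(0, 200, (64, 64))
        f1 = extract_features(img, bank=self.BANK)
        f2 = extract_features(img + 40.0, bank=self.BANK)
        assert np.max(np.abs(f1.values - f2.values)) < 1e-8

    def test_oriented_bars_peak_at_matching_orientation(self):
        img = np.zeros((64, 64))
        img[:, ::10] = 200.0  # vertical bars: intensity varies along x
        f = extract_features(img, bank=self.BANK)
        along = f["bank_t00_th000_mu0.100_energy"]  # carrier along x
        across = f["bank_t00_th090_mu0.100_energy"]
        assert along > across

    def test_scaling_image_scales_mean_features(self, rng):
        img = rng.uniform(0, 100, (64, 64))
        f1 = extract_features(img, bank=self.BANK)
        f3 = extract_features(3.0 * img, bank=self.BANK)
        means = [c for c in f1.index if c.endswith("_mean") and c.startswith("bank_")]
        assert np.allclose(f3[means].values, 3.0 * f1[means].values, rtol=1e-8)

    def test_empty_bank_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_features(rng.uniform(0, 1, (32, 32)), bank=BankConfig(thetas=(), mus=()))

    def test_segmentation_summaries_present(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        seg = np.zeros((64, 64), dtype=int)
        seg[10:14, 10:14] = 5  # a haemorrhage blob
        f = extract_features(img, seg=seg, bank=self.BANK)
        assert f["seg_haemorrhage_ncomp"] == 1.0
        assert f["he_fovea_dist"] == 1.0  # no hard exudate anywhere
        assert "lesion_total" in f.index
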