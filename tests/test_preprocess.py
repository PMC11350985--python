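"""Green-channel extraction, equalization, and multilevel DWT contracts."""

import numpy as np
import pytest

from retinograde.preprocess import (
    WaveletSpec,
    denoise_reconstruct,
    dwt2_multilevel,
    equalize_histogram,
    reconstruct,
    to_green_channel,
)


class TestGreenChannel:
    def test_pure_green_maps_to_255(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, :, 1] = 255
        out = to_green_channel(img, (32, 32))
        assert np.allclose(out, 255.0)

    def test_pure_red_maps_to_0(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, :, 0] = 255
        assert np.allclose(to_green_channel(img, (32, 32)), 0.0)

    def test_resize_to_target(self):
        img = np.random.default_rng(0).integers(0, 255, (100, 200, 3), dtype=np.uint8)
        assert to_green_channel(img, (64, 64)).shape == (64, 64)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError, match="3 channels"):
            to_green_channel(np.zeros((10, 10)), (10, 10))


class TestEqualize:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 42.0)
        assert np.array_equal(equalize_histogram(img), img)

    def test_two_level_hits_extremes(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 10.0, 20.0)
        out = equalize_histogram(img)
        assert set(np.unique(out)) == {0.0, 255.0}

    def test_ramp_yields_uniform_cdf(self):
        """Brute-force CDF of the output of a linear ramp is ~linear."""
        img = np.tile(np.arange(256, dtype=float), (4, 1))
        out = equalize_histogram(img)
        values = np.sort(out.ravel())
        # empirical CDF at each value should match its normalized rank
        ranks = np.arange(1, values.size + 1) / values.size
        assert np.max(np.abs(values / 255.0 - ranks)) < 0.01

    def test_monotone(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        out = equalize_histogram(img)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-9)


class TestDWT:
    def test_constant_image_zero_details(self):
        dec = dwt2_multilevel(np.full((32, 32), 7.0), WaveletSpec("haar", 2))
        for level in dec.details:
            for band in level:
                assert np.allclose(band, 0.0, atol=1e-10)

    @pytest.mark.parametrize("family", ["haar", "db2"])
    def test_perfect_reconstruction(self, family, rng):
        img = rng.uniform(0, 255, (64, 64))
        dec = dwt2_multilevel(img, WaveletSpec(family, 2))
        assert np.max(np.abs(reconstruct(dec) - img)) < 1e-8

    def test_haar_oracle_4x4(self):
        """1-level haar on 4x4 equals explicit row/column filter + downsample."""
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, (4, 4))
        h = np.array([1.0, 1.0]) / np.sqrt(2)  # low-pass
        g = np.array([-1.0, 1.0]) / np.sqrt(2)  # high-pass (pywt convention)

        def filt_down(rows, f):
            # periodic-free interior convolution: for length-2 filters and
            # even signals symmetric padding contributes nothing
            out = np.empty((rows.shape[0], rows.shape[1] // 2))
            for i in range(rows.shape[0]):
                for k in range(rows.shape[1] // 2):
                    out[i, k] = f[0] * rows[i, 2 * k + 1] + f[1] * rows[i, 2 * k]
            return out

        lo = filt_down(img, h)
        hi = filt_down(img, g)
        ll = filt_down(lo.T, h).T
        lh = filt_down(lo.T, g).T
        hl = filt_down(hi.T, h).T
        hh = filt_down(hi.T, g).T

        dec = dwt2_multilevel(img, WaveletSpec("haar", 1))
        cH, cV, cD = dec.details[0]
        assert np.allclose(dec.approximation, ll, atol=1e-10)
        assert np.allclose(cH, lh, atol=1e-10)
        assert np.allclose(cV, hl, atol=1e-10)
        assert np.allclose(cD, hh, atol=1e-10)

    def test_energy_conservation_haar(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        dec = dwt2_multilevel(img, WaveletSpec("haar", 3))
        assert dec.energy() == pytest.approx(np.sum(img**2), rel=1e-6)

    def test_level_shapes_halve(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        dec = dwt2_multilevel(img, WaveletSpec("haar", 3))
        # details ordered coarsest -> finest
        for i, level in enumerate(reversed(dec.details)):
            expected = int(np.ceil(64 / 2 ** (i + 1)))
            assert level[0].shape == (expected, expected)

    def test_too_many_levels_reports_max(self):
        with pytest.raises(ValueError, match="at most"):
            dwt2_multilevel(np.zeros((8, 8)), WaveletSpec("haar", 5))

    def test_additivity_of_subband_reconstructions(self, rng):
        """Inverting approximation and each detail set separately sums to x."""
        from dataclasses import replace

        img = rng.uniform(0, 255, (32, 32))
        dec = dwt2_multilevel(img, WaveletSpec("haar", 2))
        zeroed = lambda arr: np.zeros_like(arr)

        approx_only = replace(
            dec, details=[tuple(zeroed(b) for b in lev) for lev in dec.details]
        )
        total = reconstruct(approx_only)
        for li in range(dec.level):
            details = [
                tuple(b if i == li else zeroed(b) for b in lev)
                for i, lev in enumerate(dec.details)
            ]
            only_li = replace(dec, approximation=zeroed(dec.approximation), details=details)
            total = total + reconstruct(only_li)
        assert np.max(np.abs(total - img)) < 1e-8


class TestDenoise:
    def test_zero_threshold_is_identity(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        dec = dwt2_multilevel(img, WaveletSpec("haar", 2))
        assert np.max(np.abs(denoise_reconstruct(dec, "soft", 0.0) - img)) < 1e-8

    def test_huge_threshold_keeps_approximation_only(self, rng):
        from dataclasses import replace

        img = rng.uniform(0, 255, (32, 32))
        dec = dwt2_multilevel(img, WaveletSpec("haar", 2))
        out = denoise_reconstruct(dec, "soft", 1e9)
        approx_only = replace(
            dec, details=[tuple(np.zeros_like(b) for b in lev) for lev in dec.details]
        )
        assert np.allclose(out, reconstruct(approx_only), atol=1e-8)

    def test_denoising_reduces_mse_on_impulse_noise(self, rng):
        clean = np.tile(np.linspace(0, 255, 64), (64, 1))
        noisy = clean.copy()
        idx = rng.integers(0, 64, size=(60, 2))
        noisy[idx[:, 0], idx[:, 1]] += rng.choice([-80, 80], size=60)
        dec = dwt2_multilevel(noisy, WaveletSpec("haar", 2))
        out = denoise_reconstruct(dec, "soft", threshold=40.0)
        mse = lambda a, b: float(np.mean((a - b) ** 2))
        assert mse(out, clean) < mse(noisy, clean)

    def test_unknown_rule_lists_supported(self, rng):
        dec = dwt2_multilevel(rng.uniform(0, 1, (16, 16)), WaveletSpec("haar", 1))
        with pytest.raises(ValueError, match="soft"):
            denoise_reconstruct(dec, rule="fancy")
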