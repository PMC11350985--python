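"""Quantizable MLP segmenter: counts, quantization, per-pixel inference."""

import numpy as np
import pytest

from retinograde.labels import SEGMENT_CLASSES
from retinograde.quantize import representable_values
from retinograde.segment import (
    MLPConfig,
    SegmenterModel,
    calibration_patches,
    multiplier_count,
    quantize_model,
    segment,
    train_segmenter,
)


class TestMultiplierCount:
    @pytest.mark.parametrize("m, w, n, expected", [(1, 1, 1, 1), (4, 5, 3, 60)])
    def test_product(self, m, w, n, expected):
        assert multiplier_count(MLPConfig(m, w, n)) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(0, 4, 2)


def _toy_model(rng, n_in=8, n_hidden=4, n_out=3, scale=0.9):
    W1 = rng.uniform(-scale, scale, (n_in, n_hidden))
    W2 = rng.uniform(-scale, scale, (n_hidden, n_out))
    return SegmenterModel(
        config=MLPConfig(n_in, n_hidden, n_out),
        weights=[(W1, rng.normal(size=n_hidden)), (W2, rng.normal(size=n_out))],
        class_names=SEGMENT_CLASSES[:n_out],
        patch_size=3,
    )


class TestQuantizeModel:
    def test_all_zero_model_unchanged(self):
        model = SegmenterModel(
            config=MLPConfig(4, 3, 2),
            weights=[(np.zeros((4, 3)), np.zeros(3)), (np.zeros((3, 2)), np.zeros(2))],
            class_names=SEGMENT_CLASSES[:2],
        )
        q = quantize_model(model, S=3)
        for (Wq, _, scales) in q.quantized:
            assert np.allclose(Wq, 0.0)
            assert np.allclose(scales, 1.0)

    def test_already_representable_weights_zero_error(self, rng):
        grid = representable_values(3)
        W1 = rng.choice(grid, size=(6, 4))
        W2 = rng.choice(grid, size=(4, 2))
        model = SegmenterModel(
            config=MLPConfig(6, 4, 2),
            weights=[(W1, np.zeros(4)), (W2, np.zeros(2))],
            class_names=SEGMENT_CLASSES[:2],
        )
        q = quantize_model(model, S=3)
        (W1q, _, s1), (W2q, _, s2) = q.quantized
        assert np.allclose(W1q * s1, W1, atol=1e-12)
        assert np.allclose(W2q * s2, W2, atol=1e-12)

    def test_scales_are_powers_of_two(self, rng):
        model = _toy_model(rng, scale=3.0)
        q = quantize_model(model, S=3)
        for (_, _, scales) in q.quantized:
            log2 = np.log2(scales)
            assert np.allclose(log2, np.round(log2))

    def test_quantized_entries_are_representable(self, rng):
        model = _toy_model(rng, scale=2.0)
        q = quantize_model(model, S=3)
        grid = representable_values(3)
        for (Wq, _, _) in q.quantized:
            assert np.all(np.isin(np.round(Wq * 8), np.round(grid * 8)))

    def test_diffusion_reduces_mean_signed_error(self, rng):
        from retinograde.quantize import quantize_with_diffusion

        wins = 0
        for _ in range(100):
            col = rng.uniform(-0.95, 0.95, size=25)
            plain = quantize_with_diffusion(col, S=3, diffusion=False)
            diff = quantize_with_diffusion(col, S=3, diffusion=True)
            wins += abs(diff.average_error) <= abs(plain.average_error) + 1e-12
        assert wins >= 90


class TestSegmentation:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], [])

    def test_training_deterministic(self, small_dataset, preprocessed_dataset):
        samples, _ = small_dataset
        kwargs = dict(n_hidden=8, per_class=400, max_iter=60, seed=3)
        m1 = train_segmenter(samples[:4], preprocessed_dataset[:4], **kwargs)
        m2 = train_segmenter(samples[:4], preprocessed_dataset[:4], **kwargs)
        for (a, _), (b, _) in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)

    def test_segment_output_is_valid_label_map(self, segmenter, preprocessed_dataset):
        lab = segment(preprocessed_dataset[0], segmenter)
        assert lab.shape == preprocessed_dataset[0].shape
        assert set(np.unique(lab)) <= set(range(len(SEGMENT_CLASSES)))

    def test_vessel_recall_on_held_out(self, small_dataset, preprocessed_dataset, segmenter):
        samples, _ = small_dataset
        from retinograde.segment import _pixel_labels

        recalls = []
        for s, p in zip(samples[16:22], preprocessed_dataset[16:22]):
            lab = segment(p, segmenter)
            truth = _pixel_labels(s)
            vessel = truth == SEGMENT_CLASSES.index("vessel")
            recalls.append(np.mean(lab[vessel] == SEGMENT_CLASSES.index("vessel")))
        assert np.mean(recalls) > 0.7

    def test_quantized_agrees_with_float(self, small_dataset, preprocessed_dataset, segmenter):
        calib = calibration_patches(preprocessed_dataset[:3], n=8000, seed=0)
        q = quantize_model(segmenter, S=3, calibration=calib)
        agree = []
        for p in preprocessed_dataset[16:20]:
            lf = segment(p, segmenter)
            lq = segment(p, q, quantized=True)
            agree.append(np.mean(lf == lq))
        assert np.mean(agree) > 0.9

    def test_quantized_flag_requires_quantized_model(self, segmenter, preprocessed_dataset):
        with pytest.raises(ValueError, match="quantized"):
            segment(preprocessed_dataset[0], segmenter, quantized=True)

    def test_non_raster_input_rejected(self, segmenter):
        with pytest.raises(ValueError):
            segment(np.zeros((4, 4, 3)), segmenter)

    def test_serialization_roundtrip(self, segmenter, preprocessed_dataset, tmp_path):
        from retinograde.segment import load_segmenter, save_segmenter

        q = quantize_model(segmenter, S=3)
        save_segmenter(q, tmp_path / "model")
        loaded = load_segmenter(tmp_path / "model")
        p = preprocessed_dataset[16]
        assert np.array_equal(segment(p, loaded), segment(p, q))
        assert np.array_equal(
            segment(p, loaded, quantized=True), segment(p, q, quantized=True)
        )
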