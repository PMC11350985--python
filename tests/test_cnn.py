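"""Classifier forward passes against loop oracles, and swarm training."""

import numpy as np
import pandas as pd
import pytest

from retinograde.cnn import (
    CNNConfig,
    CNNWeights,
    ModuleSpec,
    conv_forward,
    forward,
    pool_forward,
    predict,
    train_classifier,
)
from retinograde.csa import SwarmParams
from retinograde.labels import GradeLabel


def conv_oracle(inputs, filters, bias):
    C, H, W = inputs.shape
    F, _, kh, kw = filters.shape
    out = np.zeros((F, H - kh + 1, W - kw + 1))
    for f in range(F):
        for i in range(H - kh + 1):
            for j in range(W - kw + 1):
                acc = 0.0
                for c in range(C):
                    for a in range(kh):
                        for b in range(kw):
                            acc += inputs[c, i + a, j + b] * filters[f, c, a, b]
                out[f, i, j] = acc + bias[f]
    return out


class TestConvForward:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(1, 6, 6))
        k = np.zeros((1, 1, 3, 3))
        k[0, 0, 1, 1] = 1.0
        out = conv_forward(x, k, np.zeros(1))
        assert np.allclose(out[0], x[0, 1:-1, 1:-1])

    def test_zero_filter_gives_activated_bias(self, rng):
        x = rng.normal(size=(2, 5, 5))
        out = conv_forward(x, np.zeros((1, 2, 3, 3)), np.array([0.7]), f=np.tanh)
        assert np.allclose(out, np.tanh(0.7))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2, 5, 5))
        k = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        assert np.max(np.abs(conv_forward(x, k, b) - conv_oracle(x, k, b))) < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv_forward(rng.normal(size=(2, 5, 5)), rng.normal(size=(1, 3, 3, 3)), np.zeros(1))


class TestPoolForward:
    def test_constant_map(self):
        x = np.full((1, 4, 4), 3.3)
        assert np.allclose(pool_forward(x, "max", 2), 3.3)
        assert np.allclose(pool_forward(x, "average", 2), 3.3)

    def test_2x2_window_values(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert pool_forward(x, "max", 2)[0, 0, 0] == 4.0
        assert pool_forward(x, "average", 2)[0, 0, 0] == 2.5

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 6, 6))
        out = pool_forward(x, "max", 2)
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    assert out[c, i, j] == x[c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max()

    def test_window_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_forward(rng.normal(size=(1, 3, 3)), "max", 4)

    def test_ragged_edge_replication(self):
        x = np.arange(9, dtype=float).reshape(1, 3, 3)
        out = pool_forward(x, "max", 2)
        assert out.shape == (1, 2, 2)
        assert out[0, 1, 1] == 8.0


class TestWeights:
    def test_flatten_unflatten_bijection(self, rng):
        cfg = CNNConfig(modules=[ModuleSpec(4, 3)], fc_widths=[8])
        shapes = CNNWeights.shapes_from_config(cfg, 36)
        vec = rng.normal(size=int(sum(np.prod(s) for s in shapes)))
        w = CNNWeights.unflatten(vec, shapes)
        assert np.array_equal(w.flatten(), vec)

    def test_wrong_length_rejected(self):
        cfg = CNNConfig(mode="mlp", fc_widths=[4])
        shapes = CNNWeights.shapes_from_config(cfg, 6)
        with pytest.raises(ValueError):
            CNNWeights.unflatten(np.zeros(3), shapes)

    def test_cnn_mode_requires_module(self):
        with pytest.raises(ValueError):
            CNNConfig(modules=[], mode="cnn")

    def test_cnn_forward_runs_on_vector_grid(self, rng):
        cfg = CNNConfig(modules=[ModuleSpec(2, 3)], fc_widths=[6])
        shapes = CNNWeights.shapes_from_config(cfg, 25)
        vec = rng.normal(size=int(sum(np.prod(s) for s in shapes)))
        out = forward(rng.normal(size=(4, 25)), CNNWeights.unflatten(vec, shapes), cfg)
        assert out.shape == (4, len(cfg.classes))


def separable_blobs(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 0.3, size=(n_per, 2))
    b = rng.normal([4, 4], 0.3, size=(n_per, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["u", "v"])
    labels = [GradeLabel("healthy", "none")] * n_per + [GradeLabel("severe_NPDR", "none")] * n_per
    return X, labels


class TestTraining:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, labels = separable_blobs()
        model = train_classifier(X, labels, steps=300, swarm_size=20, seed=1)
        preds = predict(model, X)
        assert np.mean([p == l for p, l in zip(preds, labels)]) == 1.0

    def test_seeded_training_is_reproducible(self):
        X, labels = separable_blobs()
        m1 = train_classifier(X, labels, steps=60, swarm_size=12, seed=5)
        m2 = train_classifier(X, labels, steps=60, swarm_size=12, seed=5)
        assert np.array_equal(m1.weights.flatten(), m2.weights.flatten())

    def test_final_fitness_not_worse_than_initial_best(self):
        X, labels = separable_blobs(seed=2)
        model = train_classifier(X, labels, steps=40, swarm_size=10, seed=3)
        assert model.best_fitness <= model.history[0]

    def test_single_class_rejected(self):
        X, labels = separable_blobs()
        with pytest.raises(ValueError):
            train_classifier(X, [labels[0]] * len(labels), steps=5, seed=0)

    def test_predict_checks_feature_names(self):
        X, labels = separable_blobs()
        model = train_classifier(X, labels, steps=30, swarm_size=10, seed=1)
        with pytest.raises(ValueError, match="missing features"):
            predict(model, X.rename(columns={"u": "w"}))

    def test_serialization_roundtrip(self, tmp_path):
        from retinograde.cnn import load_classifier, save_classifier

        Xb, labels = separable_blobs(seed=3)
        model = train_classifier(Xb, labels, steps=40, swarm_size=10, seed=2)
        save_classifier(model, tmp_path / "clf")
        loaded = load_classifier(tmp_path / "clf")
        assert predict(loaded, Xb) == predict(model, Xb)

    def test_row_permutation_permutes_predictions(self):
        X, labels = separable_blobs(seed=4)
        model = train_classifier(X, labels, steps=60, swarm_size=10, seed=2)
        perm = np.random.default_rng(0).permutation(len(X))
        p_all = np.array(predict(model, X), dtype=object)
        p_perm = np.array(predict(model, X.iloc[perm]), dtype=object)
        assert np.array_equal(p_perm, p_all[perm])
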