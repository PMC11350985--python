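"""Grade classifier: a small CNN / MLP head trained by chicken swarm search.

The network follows the module pattern: convolution + pooling modules
(``x_e = f(FM_e * I)``, max pooling by default) feeding fully connected
layers that emit one logit per joint DR/DME grade.  All weights — kernels,
fully-connected matrices and biases — are flattened into a single vector and
optimized with the chicken swarm algorithm (no backpropagation): fitness is
the misclassification rate on a held-out fold with a bounded cross-entropy
tie-break, minimized.

Feature-vector inputs can either be reshaped onto a zero-padded square grid
for the convolutional stack (``mode='cnn'``) or fed straight to the fully
connected layers (``mode='mlp'``), which is the configuration the pipeline
uses at its small feature counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csa import SwarmParams, csa_optimize
from .labels import JOINT_CLASSES

__all__ = [
    "ModuleSpec",
    "CNNConfig",
    "CNNWeights",
    "conv_forward",
    "pool_forward",
    "forward",
    "train_classifier",
    "predict",
    "TrainedClassifier",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One convolution + pooling module."""

    n_maps: int = 8
    kernel_size: int = 3
    pool: str = "max"  # or "average"
    pool_size: int = 2


@dataclass
class CNNConfig:
    """Architecture: conv/pool modules, fully-connected widths, class map."""

    modules: list = field(default_factory=lambda: [ModuleSpec(8), ModuleSpec(16)])
    fc_widths: list = field(default_factory=lambda: [32])
    activation: str = "tanh"
    classes: tuple = JOINT_CLASSES
    mode: str = "cnn"  # 'cnn' reshapes vectors to a grid; 'mlp' skips conv

    def __post_init__(self):
        if self.mode not in ("cnn", "mlp"):
            raise ValueError("mode must be 'cnn' or 'mlp'")
        if self.mode == "cnn" and not self.modules:
            raise ValueError("cnn mode needs at least one convolution module")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _activation(name: str):
    if name == "tanh":
        return np.tanh
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "identity":
        return lambda x: x
    raise ValueError(f"unknown activation {name!r}")


def conv_forward(inputs: np.ndarray, filters: np.ndarray, bias: np.ndarray, f=None) -> np.ndarray:
    """Valid cross-correlation of a (C,H,W) stack with (F,C,kh,kw) filters.

    Returns (F, H-kh+1, W-kw+1).  ``f`` is the activation (identity default).
    """
    inputs = np.asarray(inputs, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if inputs.ndim != 3 or filters.ndim != 4:
        raise ValueError("expected (C,H,W) inputs and (F,C,kh,kw) filters")
    C, H, W = inputs.shape
    F, Cf, kh, kw = filters.shape
    if Cf != C:
        raise ValueError(f"filter channel count {Cf} != input channels {C}")
    if kh > H or kw > W:
        raise ValueError("kernel larger than input map")
    win = np.lib.stride_tricks.sliding_window_view(inputs, (kh, kw), axis=(1, 2))
    out = np.einsum("chwij,fcij->fhw", win, filters) + np.asarray(bias)[:, None, None]
    return out if f is None else f(out)


def pool_forward(inputs: np.ndarray, kind: str = "max", window: int = 2) -> np.ndarray:
    """Non-overlapping pooling; ragged edges replicate the last row/column."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3:
        raise ValueError("expected a (C,H,W) map stack")
    C, H, W = inputs.shape
    if window > H or window > W:
        raise ValueError(f"pooling window {window} larger than map {(H, W)}")
    if kind not in ("max", "average"):
        raise ValueError("pool kind must be 'max' or 'average'")
    ph = (-H) % window
    pw = (-W) % window
    if ph or pw:
        inputs = np.pad(inputs, ((0, 0), (0, ph), (0, pw)), mode="edge")
    C, H2, W2 = inputs.shape
    blocks = inputs.reshape(C, H2 // window, window, W2 // window, window)
    if kind == "max":
        return blocks.max(axis=(2, 4))
    return blocks.mean(axis=(2, 4))


@dataclass
class CNNWeights:
    """Arrays in forward order with a fixed flatten/unflatten bijection."""

    arrays: list

    def flatten(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.arrays])

    @classmethod
    def shapes_from_config(cls, cfg: CNNConfig, n_features: int):
        shapes = []
        if cfg.mode == "cnn":
            side = int(np.ceil(np.sqrt(n_features)))
            c, h, w = 1, side, side
            for m in cfg.modules:
                shapes.append((m.n_maps, c, m.kernel_size, m.kernel_size))
                shapes.append((m.n_maps,))
                h = h - m.kernel_size + 1
                w = w - m.kernel_size + 1
                if h < 1 or w < 1:
                    raise ValueError("feature grid too small for the conv stack")
                h = int(np.ceil(h / m.pool_size))
                w = int(np.ceil(w / m.pool_size))
                c = m.n_maps
            flat = c * h * w
        else:
            flat = n_features
        for width in list(cfg.fc_widths) + [cfg.n_classes]:
            shapes.append((flat, width))
            shapes.append((width,))
            flat = width
        return shapes

    @classmethod
    def unflatten(cls, vec: np.ndarray, shapes) -> "CNNWeights":
        arrays, i = [], 0
        for shp in shapes:
            size = int(np.prod(shp))
            arrays.append(np.asarray(vec[i : i + size]).reshape(shp))
            i += size
        if i != len(vec):
            raise ValueError("weight vector length does not match the config")
        return cls(arrays)


def forward(X: np.ndarray, weights: CNNWeights, cfg: CNNConfig) -> np.ndarray:
    """Logits (n_samples, n_classes) for a feature matrix."""
    X = np.asarray(X, dtype=float)
    act = _activation(cfg.activation)
    arrays = weights.arrays
    i = 0
    if cfg.mode == "cnn":
        side = int(np.ceil(np.sqrt(X.shape[1])))
        grid = np.zeros((X.shape[0], side * side))
        grid[:, : X.shape[1]] = X
        maps = grid.reshape(-1, 1, side, side)
        for m in cfg.modules:
            filt, bias = arrays[i], arrays[i + 1]
            i += 2
            maps = np.stack(
                [pool_forward(conv_forward(s, filt, bias, act), m.pool, m.pool_size) for s in maps]
            )
        h = maps.reshape(X.shape[0], -1)
    else:
        h = X
    n_fc = len(cfg.fc_widths) + 1
    for li in range(n_fc):
        W, b = arrays[i], arrays[i + 1]
        i += 2
        h = h @ W + b
        if li < n_fc - 1:
            h = act(h)
    return h


@dataclass
class TrainedClassifier:
    config: CNNConfig
    weights: CNNWeights
    feature_names: list
    feature_mean: np.ndarray
    feature_std: np.ndarray
    best_fitness: float
    history: list
    seed: int


def _standardize(X, mean, std):
    return (X - mean) / std


def _fitness_terms(logits: np.ndarray, y: np.ndarray):
    err = float(np.mean(np.argmax(logits, axis=1) != y))
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    ce = float(-np.mean(logp[np.arange(len(y)), y]))
    return err, ce


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    X = np.asarray(features, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def train_classifier(
    features,
    labels,
    cfg: CNNConfig | None = None,
    swarm_size: int = 30,
    steps: int = 400,
    val_fraction: float = 0.25,
    restarts: int = 1,
    params: SwarmParams | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the classifier by pure chicken-swarm search over all weights.

    Fitness of a candidate weight vector is its misclassification rate plus
    a bounded cross-entropy tie-break evaluated on a stratified held-out
    fold; the tie-break is scaled below one error step, so the error rate
    always dominates and the fold's cross-entropy only orders candidates
    that misclassify equally.
    """
    F = _as_frame(features)
    if cfg is None:
        cfg = CNNConfig(mode="mlp", fc_widths=[])
    y = np.asarray([cfg.classes.index(l) if not isinstance(l, (int, np.integer)) else int(l) for l in labels])
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")

    X = F.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = _standardize(X, mean, std)

    rng = np.random.default_rng(seed)
    # stratified held-out fold
    val_idx = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        k = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(rng.permutation(idx)[:k])
    val_idx = np.asarray(sorted(val_idx))
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True

    Xv, yv = Xs[val_mask], y[val_mask]
    shapes = CNNWeights.shapes_from_config(cfg, X.shape[1])
    ds = int(sum(np.prod(s) for s in shapes))
    tie_scale = 0.5 / max(len(y), 1)  # strictly below one error step

    def objective(vec):
        w = CNNWeights.unflatten(vec, shapes)
        logits = forward(Xs, w, cfg)
        err = float(np.mean(np.argmax(logits, axis=1) != y))
        _, ce = _fitness_terms(logits[val_mask], yv)
        return err + tie_scale * ce / (1.0 + ce)

    params = params or SwarmParams()
    best_vec = best_fit = history = None
    for r in range(max(1, restarts)):  # independent swarms; keep the fittest
        vec, fit, hist = csa_optimize(
            objective, ds=ds, n=swarm_size, steps=steps, params=params,
            seed=seed + 10007 * r,
        )
        if best_fit is None or fit < best_fit:
            best_vec, best_fit, history = vec, fit, hist
    return TrainedClassifier(
        config=cfg,
        weights=CNNWeights.unflatten(best_vec, shapes),
        feature_names=list(F.columns),
        feature_mean=mean,
        feature_std=std,
        best_fitness=best_fit,
        history=history,
        seed=seed,
    )


def save_classifier(model: TrainedClassifier, path) -> None:
    """Write the weight arrays as NPZ with a JSON sidecar (config, classes)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        *model.weights.arrays,
        feature_mean=model.feature_mean,
        feature_std=model.feature_std,
    )
    sidecar = {
        "mode": model.config.mode,
        "modules": [
            [m.n_maps, m.kernel_size, m.pool, m.pool_size] for m in model.config.modules
        ],
        "fc_widths": list(model.config.fc_widths),
        "activation": model.config.activation,
        "classes": [c.name for c in model.config.classes],
        "feature_names": model.feature_names,
        "best_fitness": model.best_fitness,
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path) -> TrainedClassifier:
    import json
    from pathlib import Path

    from .labels import GradeLabel

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    blob = np.load(path.with_suffix(".npz"))
    keys = sorted(
        (k for k in blob.files if k.startswith("arr_")), key=lambda k: int(k[4:])
    )
    arrays = [blob[k] for k in keys]
    cfg = CNNConfig(
        modules=[ModuleSpec(n, k, p, s) for n, k, p, s in sidecar["modules"]],
        fc_widths=sidecar["fc_widths"],
        activation=sidecar["activation"],
        classes=tuple(GradeLabel.from_name(n) for n in sidecar["classes"]),
        mode=sidecar["mode"],
    )
    return TrainedClassifier(
        config=cfg,
        weights=CNNWeights(arrays),
        feature_names=sidecar["feature_names"],
        feature_mean=blob["feature_mean"],
        feature_std=blob["feature_std"],
        best_fitness=sidecar["best_fitness"],
        history=[],
        seed=sidecar["seed"],
    )


def predict(model: TrainedClassifier, features):
    """One grade label per row; feature names must match training."""
    F = _as_frame(features)
    missing = [n for n in model.feature_names if n not in F.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    X = F[model.feature_names].to_numpy(dtype=float)
    Xs = _standardize(X, model.feature_mean, model.feature_std)
    logits = forward(Xs, model.weights, model.config)
    idx = np.argmax(logits, axis=1)
    return [model.config.classes[i] for i in idx]
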