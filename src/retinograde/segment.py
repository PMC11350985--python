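"""Per-pixel fundus segmentation with a shift-add quantizable MLP.

A small feed-forward network classifies each pixel into one of the
anatomical / pathological classes from the surrounding patch of the
preprocessed (green-channel) raster plus two morphological top-hat views
(white top-hats at 1 px and 3 px scales pick out bright dot lesions and
separate them from single-pixel noise; the black top-hat highlights dark
dots).  Such a network with M inputs, W hidden nodes and N outputs needs
M*W*N multipliers; replacing every weight by a signed sum of at most S
powers of two (see :mod:`retinograde.quantize`) turns each multiplier into
a few shifts and adds, and the piecewise-linear tanh keeps the activation
multiplier-free as well.

Float training is delegated to scikit-learn's MLPClassifier (tanh hidden
layer) on class-balanced patches; the output biases are then tempered
toward the true pixel-class priors estimated from the training masks, which
curbs the false-positive rate on rare lesion classes.  Quantization is
applied post-training.  Weight matrices are pre-scaled per output neuron by
a power of two so every quantized entry is fractional — undoing the scale
is itself a bit-shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import black_tophat, disk, white_tophat
from sklearn.neural_network import MLPClassifier

from .labels import SEGMENT_CLASSES
from .quantize import piecewise_tanh, quantize_with_diffusion

__all__ = [
    "MLPConfig",
    "SegmenterModel",
    "multiplier_count",
    "train_segmenter",
    "quantize_model",
    "calibration_patches",
    "segment",
    "save_segmenter",
    "load_segmenter",
]


@dataclass(frozen=True)
class MLPConfig:
    """Layer sizes of the segmentation MLP and the shift-add depth S."""

    n_inputs: int
    n_hidden: int
    n_outputs: int
    max_shift: int = 3

    def __post_init__(self):
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all layer sizes must be positive")
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")


def multiplier_count(cfg: MLPConfig) -> int:
    """Number of multipliers in the float network: M * W * N."""
    return cfg.n_inputs * cfg.n_hidden * cfg.n_outputs


@dataclass
class SegmenterModel:
    """Float weights, optional quantized weights, and the pixel class map."""

    config: MLPConfig
    weights: list  # [(W1, b1), (W2, b2)], W shape (n_in, n_out)
    class_names: tuple
    patch_size: int = 9
    input_scale: float = 255.0
    quantized: list | None = None  # [(Wq, b, col_scales)] mirrors `weights`
    quantization: dict = field(default_factory=dict)
    prior_correction: float = 0.4

    @property
    def is_quantized(self) -> bool:
        return self.quantized is not None


def _channels(image: np.ndarray) -> list:
    """Input views: raster + multi-scale white top-hats + black top-hat."""
    image = np.asarray(image, dtype=float)
    return [
        image,
        white_tophat(image, disk(1)),
        white_tophat(image, disk(3)),
        black_tophat(image, disk(3)),
    ]


N_CHANNELS = 4


def _window_views(image: np.ndarray, patch: int) -> list:
    half = patch // 2
    return [
        np.lib.stride_tricks.sliding_window_view(
            np.pad(c, half, mode="reflect"), (patch, patch)
        )
        for c in _channels(image)
    ]


def _patches(image: np.ndarray, patch: int) -> np.ndarray:
    """(H*W, N_CHANNELS*patch^2) sliding multi-channel patches."""
    views = _window_views(image, patch)
    return np.concatenate([v.reshape(-1, patch * patch) for v in views], axis=1)


def _pixel_labels(sample) -> np.ndarray:
    """Per-pixel class index; later (lesion) classes overwrite earlier ones."""
    h, w = sample.image.shape[:2]
    out = np.zeros((h, w), dtype=np.int64)  # background = 0
    for idx, name in enumerate(SEGMENT_CLASSES):
        if name == "background":
            continue
        out[sample.masks[name]] = idx
    return out


def train_segmenter(
    samples,
    preprocessed,
    n_hidden: int = 64,
    patch_size: int = 9,
    per_class: int = 8000,
    max_iter: int = 1000,
    alpha: float = 0.3,
    prior_correction: float = 0.4,
    seed: int = 0,
) -> SegmenterModel:
    """Train the float segmenter on patches sampled from labeled samples.

    ``preprocessed`` holds the single-channel rasters aligned with
    ``samples`` (same H x W as the masks).  Classes are balanced by sampling
    at most ``per_class`` patch coordinates per pixel class across the whole
    set; only the selected windows are materialized, so rare lesion classes
    draw patches from every training image.  After training, the output
    biases are shifted by ``prior_correction * (log prior - log uniform)``
    toward the pixel-class priors measured on the training masks (a tempered
    Bayes adjustment for the balanced-sampling bias).
    """
    if len(samples) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)

    coords: dict[int, list] = {}
    prior_counts = np.zeros(len(SEGMENT_CLASSES))
    for si, sample in enumerate(samples):
        y_grid = _pixel_labels(sample)
        for cls in np.unique(y_grid):
            ys, xs = np.nonzero(y_grid == cls)
            prior_counts[int(cls)] += ys.size
            coords.setdefault(int(cls), []).append(
                np.column_stack([np.full(ys.size, si), ys, xs])
            )
    by_image: dict[int, list] = {}
    for cls, chunks in coords.items():
        xy = np.concatenate(chunks)
        if len(xy) > per_class:
            xy = xy[rng.choice(len(xy), size=per_class, replace=False)]
        for row in xy:
            by_image.setdefault(int(row[0]), []).append((cls, row[1], row[2]))
    X_parts, y_parts = [], []
    for si, items in by_image.items():
        items = np.asarray(items)
        views = _window_views(preprocessed[si], patch_size)
        X_parts.append(
            np.concatenate(
                [
                    v[items[:, 1], items[:, 2]].reshape(-1, patch_size * patch_size)
                    for v in views
                ],
                axis=1,
            )
        )
        y_parts.append(items[:, 0])
    X = np.concatenate(X_parts) / 255.0 - 0.5
    y = np.concatenate(y_parts)

    # strong L2 keeps weight magnitudes in a narrow band, which the coarse
    # shift-add grid quantizes far more faithfully than heavy-tailed weights
    clf = MLPClassifier(
        hidden_layer_sizes=(n_hidden,),
        activation="tanh",
        solver="adam",
        alpha=alpha,
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
        tol=1e-5,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)

    # embed into the full class space so outputs map 1:1 to SEGMENT_CLASSES
    n_classes = len(SEGMENT_CLASSES)
    W2_full = np.full((n_hidden, n_classes), 0.0)
    b2_full = np.full(n_classes, -1e3)  # classes absent from training never win
    if clf.coefs_[1].shape[1] == 1:  # sklearn binary special case
        pos = int(clf.classes_[1])
        neg = int(clf.classes_[0])
        W2_full[:, pos] = clf.coefs_[1][:, 0]
        b2_full[pos] = clf.intercepts_[1][0]
        W2_full[:, neg] = -clf.coefs_[1][:, 0]
        b2_full[neg] = -clf.intercepts_[1][0]
    else:
        for j, cls in enumerate(clf.classes_):
            W2_full[:, int(cls)] = clf.coefs_[1][:, j]
            b2_full[int(cls)] = clf.intercepts_[1][j]

    priors = prior_counts / max(prior_counts.sum(), 1)
    n_present = int((prior_counts > 0).sum())
    adjust = prior_correction * (
        np.log(np.maximum(priors, 1e-8)) - np.log(1.0 / max(n_present, 1))
    )
    b2_full = b2_full + adjust

    cfg = MLPConfig(
        n_inputs=N_CHANNELS * patch_size * patch_size,
        n_hidden=n_hidden,
        n_outputs=n_classes,
    )
    return SegmenterModel(
        config=cfg,
        weights=[
            (clf.coefs_[0].copy(), clf.intercepts_[0].copy()),
            (W2_full, b2_full),
        ],
        class_names=SEGMENT_CLASSES,
        patch_size=patch_size,
        prior_correction=prior_correction,
    )


def _quantize_column(col: np.ndarray, S: int, diffusion: bool, act=None):
    """Quantize one fan-in column, choosing its power-of-two pre-scale.

    Candidate scales are the smallest power of two covering the column and
    its two halvings (outlier weights then saturate at the representable
    extreme); the candidate minimizing reconstruction error — measured
    through the calibration activations ``act`` when given — wins.
    """
    mx = float(np.abs(col).max())
    s0 = 1.0 if mx == 0 else 2.0 ** np.ceil(np.log2(mx / 0.999999))
    best = None
    for s in sorted({max(s0, 1.0), max(s0 / 2.0, 1.0), max(s0 / 4.0, 1.0)}):
        frac = np.clip(col / s, -0.999999, 0.999999)
        rep = quantize_with_diffusion(frac, S=S, diffusion=diffusion)
        q = np.asarray(rep.quantized) * s
        if act is not None:
            err = float(np.mean((act @ (col - q)) ** 2))
        else:
            err = float(np.sum((col - q) ** 2))
        if best is None or err < best[0]:
            best = (err, s, np.asarray(rep.quantized))
    return best[1], best[2]


def quantize_model(
    model: SegmenterModel,
    S: int | None = None,
    diffusion: bool = True,
    calibration: np.ndarray | None = None,
) -> SegmenterModel:
    """Replace every weight by its shift-add form.

    Each weight-matrix column (one output neuron's fan-in) is pre-scaled by
    a power of two so entries are fractional — undoing the scale is a bit
    shift; error diffusion runs down each column in input-index order
    (adjacent patch pixels are correlated, so consecutive errors cancel).
    Biases stay float: they feed adders, not multipliers.

    ``calibration`` is an optional matrix of preprocessed input patches
    (same scaling as :func:`segment` uses).  When given, it steers the
    per-column scale choice and absorbs the mean quantization-induced logit
    shift into the biases — standard post-training quantization practice.
    """
    S = model.config.max_shift if S is None else S
    (W1, b1), (W2, b2) = model.weights
    acts = [None, None]
    if calibration is not None:
        acts[0] = calibration
        acts[1] = np.tanh(calibration @ W1 + b1)

    quantized = []
    for (W, b), act in zip(model.weights, acts):
        Wq = np.empty_like(W)
        scales = np.ones(W.shape[1])
        for j in range(W.shape[1]):
            scales[j], Wq[:, j] = _quantize_column(W[:, j], S, diffusion, act)
        quantized.append((Wq, b.copy(), scales))

    if calibration is not None:
        (W1q, _, s1), (W2q, _, s2) = quantized
        b1c = b1 + np.mean(calibration @ (W1 - W1q * s1), axis=0)
        h_q = piecewise_tanh((calibration @ W1q) * s1 + b1c)
        h_f = np.tanh(calibration @ W1 + b1)
        b2c = b2 + np.mean(h_f @ W2 - h_q @ (W2q * s2), axis=0)
        quantized = [(W1q, b1c, s1), (W2q, b2c, s2)]

    return SegmenterModel(
        config=model.config,
        weights=model.weights,
        class_names=model.class_names,
        patch_size=model.patch_size,
        input_scale=model.input_scale,
        quantized=quantized,
        quantization={
            "S": S,
            "diffusion": diffusion,
            "calibrated": calibration is not None,
        },
        prior_correction=model.prior_correction,
    )


def calibration_patches(
    preprocessed, patch_size: int = 9, n: int = 20000, seed: int = 0
) -> np.ndarray:
    """Sample scaled input patches for quantization calibration."""
    rng = np.random.default_rng(seed)
    X = np.concatenate(
        [_patches(np.asarray(p, dtype=float), patch_size) for p in preprocessed]
    )
    if len(X) > n:
        X = X[rng.choice(len(X), size=n, replace=False)]
    return X / 255.0 - 0.5


def save_segmenter(model: SegmenterModel, path) -> None:
    """Write weights as an NPZ container with a JSON config sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.quantized is not None:
        for i, (Wq, bq, s) in enumerate(model.quantized):
            arrays[f"Wq{i}"] = Wq
            arrays[f"bq{i}"] = bq
            arrays[f"scale{i}"] = s
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": {
            "n_inputs": model.config.n_inputs,
            "n_hidden": model.config.n_hidden,
            "n_outputs": model.config.n_outputs,
            "max_shift": model.config.max_shift,
        },
        "class_names": list(model.class_names),
        "patch_size": model.patch_size,
        "input_scale": model.input_scale,
        "prior_correction": model.prior_correction,
        "quantization": model.quantization,
        "n_layers": len(model.weights),
        "has_quantized": model.quantized is not None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segmenter(path) -> SegmenterModel:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    n = sidecar["n_layers"]
    weights = [(arrays[f"W{i}"], arrays[f"b{i}"]) for i in range(n)]
    quantized = None
    if sidecar["has_quantized"]:
        quantized = [
            (arrays[f"Wq{i}"], arrays[f"bq{i}"], arrays[f"scale{i}"]) for i in range(n)
        ]
    return SegmenterModel(
        config=MLPConfig(**sidecar["config"]),
        weights=weights,
        class_names=tuple(sidecar["class_names"]),
        patch_size=sidecar["patch_size"],
        input_scale=sidecar["input_scale"],
        quantized=quantized,
        quantization=sidecar["quantization"],
        prior_correction=sidecar["prior_correction"],
    )


def _forward_float(model: SegmenterModel, X: np.ndarray) -> np.ndarray:
    (W1, b1), (W2, b2) = model.weights
    h = np.tanh(X @ W1 + b1)
    return h @ W2 + b2


def _forward_quantized(model: SegmenterModel, X: np.ndarray) -> np.ndarray:
    (W1q, b1, s1), (W2q, b2, s2) = model.quantized
    h = piecewise_tanh((X @ W1q) * s1 + b1)
    return (h @ W2q) * s2 + b2


def segment(image: np.ndarray, model: SegmenterModel, quantized: bool = False) -> np.ndarray:
    """Label every pixel of a preprocessed raster; returns an int class map."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel raster, got shape {image.shape}")
    if quantized and model.quantized is None:
        raise ValueError("model has no quantized weights; call quantize_model first")
    X = _patches(image, model.patch_size) / model.input_scale - 0.5
    logits = _forward_quantized(model, X) if quantized else _forward_float(model, X)
    return np.argmax(logits, axis=1).reshape(image.shape)
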