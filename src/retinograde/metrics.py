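"""Image-quality and classification metrics.

Quality metrics compare a processed raster with its reference on the 8-bit
scale: MSE, RMSE = sqrt(MSE), PSNR = 10 log10(255^2 / MSE) dB (infinite for
identical rasters) and SSIM.  Classification metrics reduce the multi-class
confusion matrix to accuracy plus macro-averaged one-vs-rest sensitivity,
specificity, precision and F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["QualityMetrics", "compute_quality", "evaluate_metrics"]


@dataclass(frozen=True)
class QualityMetrics:
    rmse: float
    psnr: float  # dB; inf when MSE == 0
    ssim: float
    mse: float


def compute_quality(ref: np.ndarray, test: np.ndarray, data_range: float = 255.0) -> QualityMetrics:
    """All four quality metrics between two equally shaped rasters."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    mse = float(np.mean((ref - test) ** 2))
    rmse = float(np.sqrt(mse))
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(data_range**2 / mse))
    ssim = float(structural_similarity(ref, test, data_range=data_range))
    return QualityMetrics(rmse=rmse, psnr=psnr, ssim=ssim, mse=mse)


def evaluate_metrics(predicted, truth, classes=None) -> dict:
    """Accuracy and macro one-vs-rest sensitivity/specificity/precision/F1.

    ``classes`` fixes the label universe (order of the confusion matrix);
    it defaults to the labels present in ``truth`` and ``predicted``.
    Empty one-vs-rest denominators contribute zero to their macro average.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if classes is None:
        classes = sorted(set(truth) | set(predicted), key=str)
    else:
        classes = list(classes)
        stray = (set(truth) | set(predicted)) - set(classes)
        if stray:
            raise ValueError(f"labels outside the class map: {sorted(map(str, stray))}")

    idx = {c: i for i, c in enumerate(classes)}
    cm = _sk_confusion(
        [idx[t] for t in truth], [idx[p] for p in predicted], labels=range(len(classes))
    )
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    prec = _safe(tp, tp + fp)
    f1 = _safe(2 * prec * sens, prec + sens)
    return {
        "accuracy": float(tp.sum() / total),
        "sensitivity": float(sens.mean()),
        "specificity": float(spec.mean()),
        "precision": float(prec.mean()),
        "f1": float(f1.mean()),
        "confusion_matrix": cm.tolist(),
        "classes": [getattr(c, "name", str(c)) for c in classes],
    }
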