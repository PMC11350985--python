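"""Fundus image preprocessing: resize, green channel, equalization, 2D DWT.

Fundus photographs carry most vessel/lesion contrast in the green channel, so
preprocessing extracts it, equalizes the histogram for dynamic range, and
denoises in the wavelet domain: the image is decomposed into an approximation
raster plus per-level horizontal/vertical/diagonal detail rasters
(X = X_A^N + sum_i X_H^i + X_V^i + X_D^i), detail coefficients are
soft-thresholded, and the image is reconstructed.

The separable row/column transform itself is delegated to PyWavelets; this
module owns the contracts (shapes, perfect reconstruction, thresholding
rules) and the fundus-specific steps around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.transform import resize as _resize

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "to_green_channel",
    "equalize_histogram",
    "dwt2_multilevel",
    "reconstruct",
    "denoise_reconstruct",
    "preprocess_image",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Discrete wavelet family and decomposition depth.

    ``family`` is any PyWavelets discrete family name ('haar' default; 'db2'
    the length-4 alternative).  ``level`` is the number of decomposition
    levels N >= 1.  ``mode`` is the boundary padding rule.
    """

    family: str = "haar"
    level: int = 2
    mode: str = "symmetric"

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        pywt.Wavelet(self.family)  # raises for unknown families

    @property
    def wavelet(self) -> "pywt.Wavelet":
        return pywt.Wavelet(self.family)

    @property
    def scaling_sequence(self) -> np.ndarray:
        """Low-pass (scaling) analysis coefficients h."""
        return np.asarray(self.wavelet.dec_lo)

    @property
    def wavelet_sequence(self) -> np.ndarray:
        """High-pass (wavelet) analysis coefficients g."""
        return np.asarray(self.wavelet.dec_hi)


@dataclass
class WaveletDecomposition:
    """Approximation + per-level (horizontal, vertical, diagonal) details."""

    approximation: np.ndarray
    details: list  # [(H_i, V_i, D_i)] ordered coarsest -> finest
    source_shape: tuple
    spec: WaveletSpec = field(default_factory=WaveletSpec)

    @property
    def level(self) -> int:
        return len(self.details)

    def _coeff_list(self):
        return [self.approximation] + [tuple(d) for d in self.details]

    def energy(self) -> float:
        total = float(np.sum(self.approximation**2))
        for h, v, d in self.details:
            total += float(np.sum(h**2) + np.sum(v**2) + np.sum(d**2))
        return total


def to_green_channel(image: np.ndarray, target_size=(256, 256)) -> np.ndarray:
    """Extract the green channel and resize to a uniform resolution.

    Returns a float raster in [0, 255].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        n = image.shape[2] if image.ndim == 3 else 1
        raise ValueError(f"expected an RGB image with 3 channels, got {n}")
    green = image[:, :, 1].astype(float)
    if tuple(green.shape) != tuple(target_size):
        green = _resize(
            green, target_size, preserve_range=True, anti_aliasing=True
        )
    return np.clip(green, 0.0, 255.0)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Monotone CDF remapping of intensities onto the full [0, 255] range.

    A constant image is returned unchanged; with >= 2 distinct values the
    lowest maps to 0 and the highest to 255.
    """
    img = np.asarray(img, dtype=float)
    values, inverse, counts = np.unique(
        img.ravel(), return_inverse=True, return_counts=True
    )
    if values.size < 2:
        return img.copy()
    cdf = np.cumsum(counts) / img.size
    cdf_min = cdf[0]
    mapped = (cdf - cdf_min) / (1.0 - cdf_min) * 255.0
    return mapped[inverse].reshape(img.shape)


def dwt2_multilevel(img: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> WaveletDecomposition:
    """N-level separable 2D DWT (rows then columns at each level)."""
    img = np.asarray(img, dtype=float)
    max_level = pywt.dwtn_max_level(img.shape, spec.wavelet)
    if spec.level > max_level:
        raise ValueError(
            f"image {img.shape} supports at most {max_level} levels "
            f"with {spec.family!r}; requested {spec.level}"
        )
    coeffs = pywt.wavedec2(img, spec.family, mode=spec.mode, level=spec.level)
    return WaveletDecomposition(
        approximation=coeffs[0],
        details=[tuple(c) for c in coeffs[1:]],
        source_shape=img.shape,
        spec=spec,
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse multilevel transform, cropped to the source shape."""
    out = pywt.waverec2(dec._coeff_list(), dec.spec.family, mode=dec.spec.mode)
    return out[: dec.source_shape[0], : dec.source_shape[1]]


_RULES = ("soft", "hard")


def _universal_threshold(dec: WaveletDecomposition) -> float:
    """sigma_hat * sqrt(2 log n) with sigma_hat from the finest diagonal band."""
    finest_diag = dec.details[-1][2]
    sigma = float(np.median(np.abs(finest_diag))) / 0.6745
    n = int(np.prod(dec.source_shape))
    return sigma * np.sqrt(2.0 * np.log(n))


def denoise_reconstruct(
    dec: WaveletDecomposition, rule: str = "soft", threshold: float | None = None
) -> np.ndarray:
    """Threshold the detail sub-bands and invert the transform.

    ``threshold=None`` uses the universal threshold estimated from the finest
    diagonal band.  ``threshold=0`` reproduces the input exactly.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown threshold rule {rule!r}; supported: {_RULES}")
    t = _universal_threshold(dec) if threshold is None else float(threshold)
    if t <= 0:
        return reconstruct(dec)
    details = [
        tuple(pywt.threshold(band, t, mode=rule) for band in level)
        for level in dec.details
    ]
    thresholded = WaveletDecomposition(
        approximation=dec.approximation,
        details=details,
        source_shape=dec.source_shape,
        spec=dec.spec,
    )
    return reconstruct(thresholded)


def preprocess_image(
    image: np.ndarray,
    target_size=(256, 256),
    spec: WaveletSpec = WaveletSpec(),
    rule: str = "soft",
    threshold: float | None = None,
) -> np.ndarray:
    """Full preprocessing chain: green channel -> equalize -> DWT denoise."""
    g = to_green_channel(image, target_size)
    eq = equalize_histogram(g)
    dec = dwt2_multilevel(eq, spec)
    return denoise_reconstruct(dec, rule=rule, threshold=threshold)
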