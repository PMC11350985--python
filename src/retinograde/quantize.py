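"""Shift-add weight quantization with error diffusion, and a piecewise-linear tanh.

A neural-network multiplier can be replaced by a handful of bit-shifts and
additions when each weight is rounded to a signed sum of distinct negative
powers of two.  With a shift depth of ``S`` the available terms are
2^-1 .. 2^-S, so the representable set is exactly ``{k * 2^-S : |k| <= 2^S - 1}``
(every subset of the terms is a distinct numerator bit pattern).  Plain
rounding leaves a systematic signed error; diffusing each weight's error into
the quantization of the weights that follow drives the *average* signed error
toward zero.

The piecewise-linear tanh approximation keeps the whole forward pass inside
shift/add arithmetic: its slopes are 1, 1/2, 1/4 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantizedWeight",
    "QuantizationReport",
    "representable_values",
    "quantize_weight",
    "quantize_with_diffusion",
    "piecewise_tanh",
]


@dataclass(frozen=True)
class QuantizedWeight:
    """A weight expressed as ``sign * sum(2**-e for e in exponents)``."""

    sign: int
    exponents: frozenset
    value: float
    error: float  # original - value

    @property
    def n_terms(self) -> int:
        return len(self.exponents)


@dataclass
class QuantizationReport:
    """Per-weight record of a (possibly diffused) quantization pass."""

    originals: list
    quantized: list
    errors: list = field(default_factory=list)  # original - quantized
    diffusion: bool = False

    @property
    def average_error(self) -> float:
        return float(np.mean(self.errors))

    @property
    def weights(self) -> list:
        return [
            QuantizedWeight(*_decompose(q, self._S), value=q, error=e)
            for q, e in zip(self.quantized, self.errors)
        ]

    _S: int = 3


def representable_values(S: int) -> np.ndarray:
    """All signed sums of distinct terms from {2^-1, ..., 2^-S}, including 0."""
    if S < 1:
        raise ValueError("shift depth S must be >= 1")
    k = np.arange(-(2**S - 1), 2**S)
    return k / float(2**S)


def _decompose(value: float, S: int):
    """Sign and exponent set of a representable value."""
    sign = -1 if value < 0 else 1
    k = int(round(abs(value) * 2**S))
    exps = frozenset(e for e in range(1, S + 1) if (k >> (S - e)) & 1)
    return sign, exps


def _nearest(value: float, S: int) -> float:
    """Nearest representable value; ties round toward smaller magnitude.

    Out-of-range inputs (possible mid-diffusion) clamp to the extreme of the
    representable set.
    """
    step = 2.0**-S
    kmax = 2**S - 1
    scaled = value / step
    lo = np.floor(scaled)
    hi = lo + 1.0
    d_lo = scaled - lo
    d_hi = hi - scaled
    if d_lo < d_hi:
        k = lo
    elif d_hi < d_lo:
        k = hi
    else:  # equidistant: take the candidate of smaller magnitude
        k = lo if abs(lo) <= abs(hi) else hi
    k = min(max(k, -kmax), kmax)
    return float(k * step)


def quantize_weight(w: float, S: int = 3) -> QuantizedWeight:
    """Quantize a single fractional weight to its nearest shift-add value.

    Parameters
    ----------
    w : float
        Weight with ``|w| < 1``.  Larger weights must be pre-scaled by the
        caller (see :func:`retinograde.segment.quantize_model`).
    S : int
        Maximum number of shift-and-add terms (shift depth).
    """
    if S < 1:
        raise ValueError("shift depth S must be >= 1")
    if abs(w) >= 1.0:
        raise ValueError(
            f"|w| = {abs(w)} >= 1: pre-scale the layer so weights are fractional"
        )
    q = _nearest(w, S)
    sign, exps = _decompose(q, S)
    return QuantizedWeight(sign=sign, exponents=exps, value=q, error=w - q)


def quantize_with_diffusion(
    ws, S: int = 3, diffusion: bool = True
) -> QuantizationReport:
    """Quantize an ordered weight sequence, optionally diffusing the errors.

    With diffusion on, the value actually quantized for weight ``i`` is
    ``w_i`` plus the cumulative signed errors of all earlier weights; the
    recorded per-weight error is always measured against the *original*
    weight.  Without diffusion each weight is quantized independently.
    """
    ws = [float(w) for w in np.asarray(ws, dtype=float).ravel()]
    if not ws:
        raise ValueError("empty weight sequence")
    for w in ws:
        if abs(w) >= 1.0:
            raise ValueError(
                f"|w| = {abs(w)} >= 1: pre-scale the layer so weights are fractional"
            )
    quantized, errors = [], []
    carry = 0.0
    for w in ws:
        target = w + carry if diffusion else w
        q = _nearest(target, S)
        err = w - q
        quantized.append(q)
        errors.append(err)
        if diffusion:
            carry += err
    return QuantizationReport(
        originals=ws, quantized=quantized, errors=errors, diffusion=diffusion, _S=S
    )


def piecewise_tanh(x):
    """Piecewise-linear approximation of tanh with shift/add-only slopes.

    ``f(|x|)`` is |x| on [0, 0.5); 0.5 + (|x|-0.5)/2 on [0.5, 1);
    0.75 + (|x|-1)/4 on [1, 2); and 1 beyond.  Odd, continuous,
    non-decreasing, bounded by +/-1, and within 0.06 of tanh everywhere.
    """
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    f = np.where(
        a < 0.5,
        a,
        np.where(a < 1.0, 0.5 + (a - 0.5) / 2.0, np.where(a < 2.0, 0.75 + (a - 1.0) / 4.0, 1.0)),
    )
    out = np.sign(x) * f
    return float(out) if out.ndim == 0 else out
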