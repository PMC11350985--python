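"""Shift-add weight quantization with and without error diffusion.

Quantizes the weight sequence (0.8000, 0.4250, 0.4050) with a shift depth
of 3 (terms 2^-1, 2^-2, 2^-3), showing how diffusing each weight's error
into the next quantization shrinks the average signed error by more than
an order of magnitude, and evaluates the multiplier-free piecewise tanh.
"""

import numpy as np

from retinograde import piecewise_tanh, quantize_weight, quantize_with_diffusion

for w in (0.8735, 0.3811):
    q = quantize_weight(w, S=3)
    terms = " + ".join(f"2^-{e}" for e in sorted(q.exponents))
    print(f"{w:.4f} -> {q.value:.4f} = {terms}   (error {q.error:+.4f})")

ws = (0.8000, 0.4250, 0.4050)
for diffusion in (False, True):
    rep = quantize_with_diffusion(ws, S=3, diffusion=diffusion)
    mode = "with diffusion   " if diffusion else "without diffusion"
    errs = ", ".join(f"{e:+.4f}" for e in rep.errors)
    print(f"{mode}: errors [{errs}]  average {rep.average_error:+.4f}")

x = np.linspace(-4, 4, 801)
gap = np.max(np.abs(piecewise_tanh(x) - np.tanh(x)))
print(f"piecewise tanh max deviation from tanh on [-4, 4]: {gap:.4f}")
# Diffusion drops the average signed error from +0.0433 to +0.0017 while
# each weight still uses at most three shift-add terms.
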