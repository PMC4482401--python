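"""Fit the per-branch pattern-count law M(n) = a·n·ln n + b.

Noisy per-branch samples generated from known constants (a = 2, b = 5) are
refitted; the n·log n model is compared against linear and quadratic
alternatives by adjusted R², which penalises the quadratic's extra
coefficient.
"""

import numpy as np

from dendromem import fit_mlaw, mlaw_predict

rng = np.random.default_rng(42)
n = rng.integers(2, 200, size=100)
M = (2.0 * n * np.log(n) + 5.0) * (1 + 0.05 * rng.standard_normal(100))
samples = list(zip(n, M))

for model in ("nlogn", "linear", "quadratic"):
    fit = fit_mlaw(samples, model)
    print(f"{model:9s}: adj R^2 = {fit.adj_r2:.4f}   coefficients = "
          + ", ".join(f"{c:.3f}" for c in fit.coefficients))

fit = fit_mlaw(samples, "nlogn")
print(f"\nrecovered a = {fit.a:.3f} (true 2), b = {fit.b:.2f} (true 5)")
# once fitted, the law predicts a whole neuron's M from its spine counts alone
counts = [12, 40, 7, 95]
print(f"predicted M for branches {counts}: "
      f"{mlaw_predict(counts, fit.a, fit.b):.0f}")
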