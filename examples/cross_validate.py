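"""Stabilise a cross-validated accuracy estimate by repeating the split.

A single 10-fold split gives a noisy VEcv; repeating it 100 times and
averaging the pooled per-repetition scores gives a stable value with an
honest spread.
"""

import numpy as np

from vecv import assess


class OLS1D:
    """One-feature least squares, the simplest predictor obeying fit/predict."""

    def fit(self, X, y):
        self.coef_ = np.polyfit(np.ravel(X), y, 1)
        return self

    def predict(self, X):
        return np.polyval(self.coef_, np.ravel(X))


rng = np.random.default_rng(0)
x = np.linspace(0, 10, 60)
y = 3.0 + 1.2 * x + rng.normal(0, 1.5, size=60)

once = assess(OLS1D(), x, y, k=10, repetitions=1, seed=1)
many = assess(OLS1D(), x, y, k=10, repetitions=100, seed=1)
loo = assess(OLS1D(), x, y, k=len(y), seed=123)  # leave-one-out: deterministic

print(f"single 10-fold:     VEcv = {once.vecv_mean:6.2f}%")
print(f"100 x 10-fold:      VEcv = {many.vecv_mean:6.2f}% +/- {many.vecv_sd:.2f}")
print(f"                    E1   = {many.e1_mean:6.2f}% +/- {many.e1_sd:.2f}")
print(f"leave-one-out:      VEcv = {loo.reports[0].vecv_pct:6.2f}% (seed-independent)")

# The repeated mean is the stabilised accuracy; the sd quantifies how much
# a single cross-validation split can mislead.
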