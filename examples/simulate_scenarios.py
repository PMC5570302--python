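"""Sweep the prediction slope and watch the measures diverge from r.

Scenario 1 scales perfect predictions by a slope beta (predicted = beta*x).
Accuracy collapses as beta leaves 1, but Pearson r stays exactly 1.
"""

import vecv

res = vecv.sweep(1, grid=[0.1, 0.3, 0.6, 0.9, 1.0, 1.2])
print("slope   VEcv%      E1%      dr%      r")
for slope, rep in zip(res.grid, res.reports):
    print(f"{slope:5.2f} {rep.vecv_pct:8.2f} {rep.e1_pct:8.2f} {rep.dr_pct:8.2f} {rep.r:7.4f}")

# Note VEcv = -240.76% at slope 0.1: the "model" is far worse than just
# predicting the mean, yet r still reports a perfect 1.0.

# with noise the curves soften but the story is identical:
noisy = vecv.sweep(3, grid=[0.1, 0.6, 1.0], noise_sd=2.0, seed=0)
print("\nnoisy scenario 3 (sd=2, one realization):")
for slope, rep in zip(noisy.grid, noisy.reports):
    print(f"{slope:5.2f} VEcv={rep.vecv_pct:8.2f}%  r={rep.r:.4f}")
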