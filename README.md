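# vecv — accuracy measures for numerical predictions, and why r is not one

`vecv` is a validation-metrics toolkit for anyone who evaluates predictive
models of numerical data (spatial interpolation, environmental modelling,
epidemiological prediction, machine-learning regression). It exists because
the two most popular "accuracy" statistics — Pearson's *r* and *r²* —
measure linear association with the *fitted* line through the
(observed, predicted) cloud, not agreement with the *identity* line
`predicted = observed`, and therefore cannot see systematic bias at all.

The package provides:

- **Accuracy measures** computed against the identity line, for observed
  values *yᵢ*, predictions *ŷᵢ* and observed mean *ȳ*:

  - variance explained by predictive models based on cross-validation

    `VEcv = (1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ)²) · 100 %`

  - Legates–McCabe efficiency, its absolute-value analogue

    `E1 = (1 − Σ|yᵢ−ŷᵢ| / Σ|yᵢ−ȳ|) · 100 %`

  - Willmott's refined index of agreement `dr` (= `E1` when `E1 ≥ 0`,
    otherwise `(Σ|yᵢ−ȳ|/Σ|yᵢ−ŷᵢ| − 1)·100`, bounded in (−100, 0))

  All three are 100 % only for a perfect match and 0 % for the global-mean
  predictor; `VEcv` and `E1` are unbounded below, which is a feature — a
  model can be arbitrarily worse than predicting the mean.

- **The error-measure family** MAE, MSE, RMSE, RMAE, RRMSE, SRMSE, MSRE,
  plus Pearson's *r*, *r²* and the slope-weighted *r*, all in one
  `full_report`.

- **An exact conversion algebra**: because `MSE = s²(1−VEcv/100)(n−1)/n`,
  any squared-error measure can be translated to and from VEcv using only
  the validation set's `(n, s, mean)` — so errors published without raw
  data become directly comparable on one accuracy scale. MAE/RMAE
  conversions use the empirical ratio `RMSE/MAE = √2.0572` and are flagged
  as such.

- **A four-scenario simulation study** (`sweep`, `run_study`) that makes
  the case quantitatively: predictions `βx`, `(1−β)x̄ + βx`, and both plus
  Gaussian noise, swept over a slope grid. On the noiseless sweeps *r* is
  identically 1 at every slope while VEcv falls 100 → 95.79 → 32.69 →
  −106.14 → −240.76 % as β drops 1 → 0.9 → 0.6 → 0.3 → 0.1.

- **Repeated k-fold cross-validation scoring** (`assess`) with pooled
  out-of-fold predictions and mean ± sd of VEcv/E1 across repetitions.

## Worked example

```python
import numpy as np
from vecv import full_report

observed = np.arange(1, 31, dtype=float)
predicted = 0.9 * observed          # model under-predicts by 10%

rep = full_report(observed, predicted)
print(rep.vecv_pct, rep.e1_pct, rep.r)
```

prints

```
95.79310344827586 79.33333333333334 1.0
```

A 10 % systematic under-prediction costs 4.2 points of VEcv and 20.7
points of E1 — yet `r = 1.0` exactly, because the points still lie on a
straight line. Running `python examples/simulate_scenarios.py` extends
this to the full slope sweep (at slope 0.1 the model is far worse than
predicting the mean, `VEcv = −240.76 %`, while r still says 1.0); the other
scripts in `examples/` demonstrate the conversion algebra, the full study
and cross-validation stabilisation.

A thin CLI mirrors the library:

```bash
vecv metrics pairs.csv                 # paired CSV -> full report (JSON)
vecv convert --measure rmse --value 1.78 --n 30 --sd 8.8 --mean 15.5
vecv simulate --scenario 1 --grid 0.1:1.2:0.01
vecv study --out study_output
vecv cv folded_predictions.csv
```

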