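# Methods

## Measures

All measures operate on a validation set of paired observed values *yᵢ*
and predictions *ŷᵢ*, i = 1..n, with observed mean *ȳ* and sample
standard deviation *s* (n−1 denominator throughout; this choice is what
makes the conversion identities below exact). Accuracy is defined as
agreement with the identity line `ŷ = y`:

| measure | definition | scale |
|---|---|---|
| MAE | Σ\|yᵢ−ŷᵢ\|/n | units of y |
| MSE | Σ(yᵢ−ŷᵢ)²/n | units² |
| RMSE | √MSE | units |
| RMAE, RRMSE | 100·MAE/ȳ, 100·RMSE/ȳ | % |
| SRMSE, MSRE | RMSE/s, MSE/s² | unitless |
| VEcv | 100·(1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²) | % |
| E1 | 100·(1 − Σ\|yᵢ−ŷᵢ\|/Σ\|yᵢ−ȳ\|) | % |
| dr | E1 if E1 ≥ 0, else 100·(Σ\|yᵢ−ȳ\|/Σ\|yᵢ−ŷᵢ\| − 1) | % |
| r, r² | Pearson correlation of (y, ŷ) and its square | unitless |
| weighted r | r·b for 0 < b ≤ 1, r/b for b > 1; b = OLS slope of ŷ on y | unitless |

VEcv and E1 are 100 only for a perfect match, 0 for the global-mean
predictor, and unbounded below. r, by contrast, is invariant under any
positive affine transform of either argument — the "affine blindness"
that disqualifies it as an accuracy measure and motivates this package.

The weighted-r formula is not fixed by the literature this package
follows; the adopted rule (damping factor min(|b|, 1/|b|)) is the
standard slope-weighting proposal, extended continuously to negative
slopes. It is exposed for completeness and comparison, not endorsed.

Percent-scaled measures are always reported on the printed scale
(95.79, not 0.9579). Undefined situations are never silently coerced:
constant observations invalidate the variance-normalised measures, a
constant prediction vector makes r undefined (not zero), and a zero
observed mean invalidates only RMAE/RRMSE; `full_report` marks such
entries as null with a reason instead of dropping them. Rows with missing
values are rejected at construction — no silent pairwise deletion.

## Conversion algebra

Since Σ(yᵢ−ȳ)² = (n−1)s², the definition of VEcv rearranges to exact
identities for every squared-error measure: MSE = s²(1−VEcv/100)(n−1)/n,
and RMSE, SRMSE, MSRE, RRMSE follow by their definitions. These hold for
any dataset and are tested to 1e-10 relative tolerance against direct
computation on randomized data; their inverses are algebraic and
round-trip exactly.

MAE is not determined by the SSE. The MAE/RMAE conversions assume the
empirically near-constant ratio RMSE/MAE = √c with c = 2.0572, giving
MAE = s·√((1−VEcv/100)(n−1)/(c·n)). The placement of c inside the root is
a design choice (it keeps RMSE/MAE constant and mirrors the structure of
the exact rows); c is a parameter of the API and every MAE-family
conversion is flagged "empirical" in the output.

## Simulation scenarios

The generator emulates a validation exercise in which predictions are
linearly related to observations with slope β:

1. `ŷ = βx` (through the origin),
2. `ŷ = (1−β)x̄ + βx` (the line pivots about the observed mean, so β = 0
   is exactly the global-mean predictor),
3. scenario 1 + ε, ε ~ iid N(0, σ²),
4. scenario 2 + ε.

Defaults: the observed vector is the integer sequence 1..30 (n = 30) and
σ = 2 for the noisy scenarios; the slope grids are [0.1, 1.2] for
scenarios 1/3 and [0, 1.2] for 2/4, at step 0.01 with the slopes
{0.3, 0.6, 0.9, 1.0} always included. Under these defaults the noiseless
curves are closed-form — scenario 1: VEcv(β) = (1 − (1−β)²·Σx²/Σ(x−x̄)²)·100;
scenario 2: VEcv(β) = (1 − (1−β)²)·100 independent of x — and the test
suite asserts the sweeps against these forms to 1e-10. Noise uses numpy's
PCG64 generator with an explicit seed; within one sweep a single ε vector
is drawn and reused across the grid, so each noisy curve is one smooth
realization. The study's VEcv-vs-E1 comparison additionally runs
scenario 4 at (n=300, σ=2) and (n=300, σ=3).

What the generator does not emulate: heteroscedastic or non-Gaussian
errors, nonlinear prediction bias, autocorrelated validation samples, or
any real measurement process. Passing tests therefore demonstrate the
algebraic and distributional behaviour of the measures under a linear
bias + iid noise model, not performance claims about any real dataset.

## Numerical choices

- Pearson r is clipped into [−1, 1] after computation to absorb last-ulp
  excursions; it agrees with `scipy.stats.pearsonr` to 1e-12 (tested).
- Rank agreement (`rank_agreement`) rounds measure columns to 9 decimals
  before ranking so that analytically tied values — e.g. the slope pairs
  1±δ of a noiseless sweep, where both VEcv and E1 are exact functions of
  |1−β| — are ranked as ties rather than being ordered by floating-point
  noise; identical rank vectors return exactly 1.0.
- Zero crossings of the accuracy curves are located by linear
  interpolation between grid points.
- Sweep grids must be strictly increasing; empty grids and slopes outside
  a scenario's permitted range are rejected.

## Cross-validation scoring

`assess` repeats k-fold cross-validation (default k = 10, 100
repetitions) and scores each repetition by pooling the out-of-fold
predictions of all folds into one validation set before computing the
measures. Pooling is the correct granularity for VEcv because its
denominator is the variance of the whole validation set; averaging
per-fold scores would normalise each fold by a different variance. The
stabilised value is reported as the mean across repetitions with its
sample sd (per-repetition reports are kept, so a median summary is one
line away). Leave-one-out (k = n) has a unique partition: it is
deterministic, independent of the seed, and forces a single repetition.
Fold sizes differ by at most one; every observation is scored exactly
once per repetition (enforced, and proven in tests by an identity
predictor scoring VEcv = 100 in every repetition).

## Known limitations and observed deviations

- With noise, VEcv and E1 do not rank a fine slope grid *identically*:
  within one ε realization their optimal slopes differ slightly, so a few
  adjacent near-peak slopes swap order and the Spearman agreement on the
  default noisy sweeps is ≈ 0.999 rather than exactly 1. The noiseless
  sweeps agree exactly. This is a real property of the measures, reported
  as computed.
- The three accuracy measures' zero crossings coincide only approximately
  on scenario 1 (VEcv at β ≈ 0.5125, E1/dr at β ≈ 0.5161 for x = 1..30);
  the study reports the measured crossings and the tests assert
  coincidence within one grid step.
- Noisy-scenario reference values are single realizations of an unknown
  RNG; they are validated distributionally (inside the central 99 %
  interval over 1000 seeds), not reproduced bit-for-bit.
- The MAE/RMAE conversion constant is empirical and dataset-population
  specific; conversions carry an explicit exactness flag so downstream
  users can ignore the empirical ones.
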