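"""Repeated k-fold cross-validation scoring with pooled out-of-fold predictions.

A single k-fold split is a random partition, so the accuracy it yields is
itself a random variable; repeating the cross-validation (100 times by
default) and reporting the mean and spread of VEcv/E1 across repetitions
stabilises the assessment.  Leave-one-out has no randomness and needs no
repetition.

Scoring is pooled-then-score: within one repetition the out-of-fold
predictions for all folds are concatenated into a single validation set
and the measures computed once on it.  This matches the definition of
VEcv, whose denominator is the variance of the whole validation set —
averaging per-fold scores would use k different denominators.

The predictor contract is the familiar estimator protocol: an object (or
factory returning one) with ``fit(X, y)`` and ``predict(X)``.  This module
scores predictions; it ships no learners beyond two trivial reference
predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, VecvError
from .metrics import MeasureReport, PairedData, full_report

__all__ = [
    "kfold_indices",
    "assess",
    "assess_folded",
    "CVResult",
    "FoldedPredictions",
    "MeanPredictor",
    "IdentityPredictor",
]

DEFAULT_K = 10
DEFAULT_REPETITIONS = 100


def kfold_indices(n: int, k: int, seed: int | None = 0) -> list[np.ndarray]:
    """Random partition of range(n) into k folds whose sizes differ by at most 1.

    ``k = n`` gives leave-one-out.  The shuffle is driven by ``seed``; pass
    None for nondeterministic folds.
    """
    if not 2 <= k <= n:
        raise InputError(f"k must satisfy 2 <= k <= n; got k={k}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


class MeanPredictor:
    """Predicts the training-set mean of y for every case (the no-skill baseline)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class IdentityPredictor:
    """Predicts the (single) input feature itself; useful as a perfect-model control
    when the feature equals the target."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, 0] if X.ndim == 2 else X


@dataclass(frozen=True)
class FoldedPredictions:
    """Out-of-fold predictions for one repetition of a k-fold split."""

    observed: np.ndarray
    predicted: np.ndarray
    fold: np.ndarray
    repetition: int = 0

    def __post_init__(self):
        n = len(self.observed)
        if not (len(self.predicted) == len(self.fold) == n):
            raise InputError("observed, predicted and fold must have equal length")


@dataclass(frozen=True)
class CVResult:
    """Stabilised cross-validation assessment.

    ``reports`` holds one pooled MeasureReport per repetition; the summary
    statistics are the across-repetition mean and sample sd of VEcv and E1
    (mean reported as the stabilised value; per-repetition values remain
    available for medians or other summaries).
    """

    reports: Sequence[MeasureReport]
    k: int
    repetitions: int
    seed: int | None

    def _col(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.reports], dtype=float)

    @property
    def vecv_mean(self) -> float:
        return float(self._col("vecv_pct").mean())

    @property
    def vecv_sd(self) -> float:
        v = self._col("vecv_pct")
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def e1_mean(self) -> float:
        return float(self._col("e1_pct").mean())

    @property
    def e1_sd(self) -> float:
        v = self._col("e1_pct")
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"repetition": i, **r.to_dict()} for i, r in enumerate(self.reports)])


def _pooled_report(X, y, predictor_factory, folds, rep, k) -> MeasureReport:
    pooled = np.empty_like(y, dtype=float)
    seen = np.zeros(y.shape[0], dtype=bool)
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(y.shape[0]), test_idx, assume_unique=False)
        model = predictor_factory()
        try:
            model.fit(X[train_idx], y[train_idx])
            pred = np.asarray(model.predict(X[test_idx]), dtype=float)
        except Exception as exc:  # surface where it broke
            raise VecvError(
                f"predictor failed on repetition {rep}, fold {fold_id} (k={k}): {exc}"
            ) from exc
        pooled[test_idx] = pred
        seen[test_idx] = True
    if not seen.all():
        raise VecvError("internal error: some observations received no out-of-fold prediction")
    return full_report(PairedData(y, pooled))


def assess(
    predictor,
    X,
    y,
    k: int = DEFAULT_K,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int | None = 0,
) -> CVResult:
    """Repeated k-fold cross-validation of a predictor, scored on pooled folds.

    Parameters
    ----------
    predictor : estimator with ``fit(X, y)``/``predict(X)``, or a zero-argument
        callable returning a fresh one per fold (use a factory for estimators
        whose ``fit`` does not reset state).
    X : feature array, shape (n,) or (n, p).
    y : observed target values, shape (n,).
    k : folds per repetition; ``k = len(y)`` is leave-one-out, which is
        deterministic and forces ``repetitions = 1``.
    repetitions : number of independent k-fold splits; each yields one pooled
        MeasureReport, and the mean ± sd of VEcv/E1 across them is the
        stabilised assessment.
    seed : seeds the fold shuffles (one child seed per repetition).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise InputError("y must be one-dimensional")
    if X.shape[0] != y.shape[0]:
        raise InputError("X and y must agree on the number of cases")
    if repetitions < 1:
        raise InputError("repetitions must be >= 1")
    n = y.shape[0]
    if not 2 <= k <= n:
        raise InputError(f"k must satisfy 2 <= k <= n; got k={k}, n={n}")

    if callable(predictor) and not hasattr(predictor, "fit"):
        factory = predictor
    else:
        proto = predictor

        def factory():
            return proto

    loo = k == n
    if loo:
        repetitions = 1  # partition into singletons is unique; no randomness to average over
    rng = np.random.default_rng(seed)
    reports = []
    for rep in range(repetitions):
        folds = (
            [np.array([i]) for i in range(n)]
            if loo
            else kfold_indices(n, k, int(rng.integers(0, 2**31 - 1)))
        )
        reports.append(_pooled_report(X, y, factory, folds, rep, k))
    return CVResult(reports, k=k, repetitions=repetitions, seed=seed)


def assess_folded(tables: Sequence[FoldedPredictions] | pd.DataFrame) -> CVResult:
    """Score externally produced fold-labelled predictions.

    Accepts either FoldedPredictions objects (one per repetition) or a long
    DataFrame with columns observed, predicted, fold, repetition.  Each
    repetition's rows are pooled into one validation set and scored.
    """
    if isinstance(tables, pd.DataFrame):
        required = {"observed", "predicted", "fold", "repetition"}
        missing = required - set(tables.columns)
        if missing:
            raise InputError(f"folded prediction table lacks column(s) {sorted(missing)}")
        tables = [
            FoldedPredictions(
                grp["observed"].to_numpy(float),
                grp["predicted"].to_numpy(float),
                grp["fold"].to_numpy(),
                repetition=int(rep),
            )
            for rep, grp in tables.groupby("repetition")
        ]
    if not tables:
        raise InputError("no repetitions supplied")
    reports = [full_report(PairedData(t.observed, t.predicted)) for t in tables]
    k = len(np.unique(tables[0].fold))
    return CVResult(reports, k=k, repetitions=len(tables), seed=None)
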