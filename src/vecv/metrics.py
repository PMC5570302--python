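"""Accuracy and error measures for paired observed/predicted values.

The central quantity is VEcv, the variance explained by a predictive model
in a validation set::

    VEcv = (1 - sum((y_i - yhat_i)^2) / sum((y_i - ybar)^2)) * 100  (%)

where ``y_i`` are the observed values of the validation samples, ``yhat_i``
the predictions for them and ``ybar`` the observed mean.  Unlike Pearson's
``r`` it compares predictions with the identity line ``yhat = y``, so any
systematic under- or over-prediction lowers it.  It is 100% only for a
perfect match, 0% for the global-mean predictor, and can be arbitrarily
negative.  Its absolute-value analogue is the Legates-McCabe efficiency
``E1``; the refined index of agreement ``dr`` equals ``E1`` when ``E1 >= 0``
and rescales negative efficiencies into (-100, 0).

All efficiency-type measures (``vecv``, ``e1``, ``dr``) and the relative
errors (``rmae``, ``rrmse``) are returned on the 0-100 percent scale;
``r``, ``r^2``, ``srmse`` and ``msre`` are unitless ratios; ``mae``,
``mse`` and ``rmse`` carry the units (or squared units) of the variable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InputError, UndefinedMeasureError

__all__ = [
    "PairedData",
    "MeasureReport",
    "ErrorMeasures",
    "vecv",
    "e1",
    "dr",
    "pearson_r",
    "weighted_r",
    "ols_slope",
    "error_measures",
    "full_report",
    "REPORT_FIELDS",
]


@dataclass(frozen=True)
class PairedData:
    """Observed and predicted vectors for one validation exercise.

    Both vectors must have the same length ``n >= 2`` and contain no
    missing or non-finite entries: validation pairs are complete by
    construction, and rows with a missing entry are rejected outright
    rather than silently dropped.
    """

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        pred = np.asarray(self.predicted, dtype=float)
        if obs.ndim != 1 or pred.ndim != 1:
            raise InputError("observed and predicted must be one-dimensional vectors")
        if obs.shape[0] != pred.shape[0]:
            raise InputError(
                f"length mismatch: {obs.shape[0]} observed vs {pred.shape[0]} predicted"
            )
        if obs.shape[0] < 2:
            raise InputError("at least two observation/prediction pairs are required")
        bad = ~(np.isfinite(obs) & np.isfinite(pred))
        if bad.any():
            rows = np.flatnonzero(bad)[:5].tolist()
            raise InputError(f"missing or non-finite values at row(s) {rows}")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)

    @property
    def n(self) -> int:
        return self.observed.shape[0]

    @property
    def mean_observed(self) -> float:
        return float(self.observed.mean())

    @property
    def s(self) -> float:
        """Sample standard deviation of the observed values (n-1 denominator)."""
        return float(self.observed.std(ddof=1))


def _as_pairs(pairs, predicted=None) -> PairedData:
    if predicted is not None:
        return PairedData(np.asarray(pairs), np.asarray(predicted))
    if isinstance(pairs, PairedData):
        return pairs
    raise InputError("expected a PairedData or two vectors (observed, predicted)")


def _ss_about_mean(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def vecv(pairs, predicted=None) -> float:
    """Variance explained by the predictive model, in percent.

    ``100 * (1 - SSE / SS_tot)`` with SSE the squared prediction errors and
    SS_tot the observed total sum of squares about the mean.  Ranges over
    ``(-inf, 100]``; 0 for the global-mean predictor.

    Raises :class:`UndefinedMeasureError` if the observed values are constant.
    """
    p = _as_pairs(pairs, predicted)
    ss_tot = _ss_about_mean(p.observed)
    if ss_tot == 0.0:
        raise UndefinedMeasureError("vecv", "observed values have zero variance")
    sse = float(((p.observed - p.predicted) ** 2).sum())
    return (1.0 - sse / ss_tot) * 100.0


def e1(pairs, predicted=None) -> float:
    """Legates-McCabe efficiency in percent: the absolute-value analogue of VEcv."""
    p = _as_pairs(pairs, predicted)
    sad_tot = float(np.abs(p.observed - p.observed.mean()).sum())
    if sad_tot == 0.0:
        raise UndefinedMeasureError("e1", "observed values have zero absolute deviation")
    sae = float(np.abs(p.observed - p.predicted).sum())
    return (1.0 - sae / sad_tot) * 100.0


def dr(pairs, predicted=None) -> float:
    """Refined index of agreement in percent.

    Equals :func:`e1` when that is non-negative; otherwise remaps it into
    ``(-100, 0)`` via ``(SAD_tot / SAE - 1) * 100``.
    """
    p = _as_pairs(pairs, predicted)
    val = e1(p)
    if val >= 0.0:
        return val
    sad_tot = float(np.abs(p.observed - p.observed.mean()).sum())
    sae = float(np.abs(p.observed - p.predicted).sum())
    return (sad_tot / sae - 1.0) * 100.0


def pearson_r(pairs, predicted=None) -> float:
    """Pearson product-moment correlation between observed and predicted values.

    Measures linear association with the fitted line, *not* agreement with
    the identity line: it is invariant under positive affine transforms of
    either argument, which is exactly why it mis-states predictive accuracy.

    Raises :class:`UndefinedMeasureError` when either vector is constant.
    """
    p = _as_pairs(pairs, predicted)
    x = p.observed - p.observed.mean()
    y = p.predicted - p.predicted.mean()
    sx = float((x * x).sum())
    sy = float((y * y).sum())
    if sx == 0.0:
        raise UndefinedMeasureError("r", "observed values have zero variance")
    if sy == 0.0:
        raise UndefinedMeasureError("r", "predicted values are constant")
    return float(np.clip((x * y).sum() / math.sqrt(sx * sy), -1.0, 1.0))


def ols_slope(pairs, predicted=None) -> float:
    """OLS slope of predicted on observed: cov(y, yhat) / var(y)."""
    p = _as_pairs(pairs, predicted)
    x = p.observed - p.observed.mean()
    sx = float((x * x).sum())
    if sx == 0.0:
        raise UndefinedMeasureError("slope", "observed values have zero variance")
    return float((x * (p.predicted - p.predicted.mean())).sum() / sx)


def weighted_r(pairs, predicted=None) -> float:
    """Slope-weighted correlation: r damped by the regression slope's departure from 1.

    ``wr = r * b`` for ``0 < b <= 1`` and ``wr = r / b`` for ``b > 1``, with
    ``b`` the OLS slope of predicted on observed (for negative ``b`` the
    damping factor uses ``|b|``).  Always ``|wr| <= |r|``, with equality at
    ``b = 1``.  This follows the definition proposed in the literature to
    patch r's affine blindness; it remains a goodness-of-fit quantity, not
    an accuracy measure.
    """
    p = _as_pairs(pairs, predicted)
    r = pearson_r(p)
    b = abs(ols_slope(p))
    factor = b if b <= 1.0 else 1.0 / b
    return r * factor


@dataclass(frozen=True)
class ErrorMeasures:
    """The MAE/MSE error-measure family on one validation set.

    ``rmae_pct``/``rrmse_pct`` are None (with a reason in ``undefined``)
    when the observed mean is zero; the remaining entries are always
    defined for valid input (``srmse``/``msre`` additionally require
    positive observed variance).
    """

    mae: float
    mse: float
    rmse: float
    rmae_pct: float | None
    rrmse_pct: float | None
    srmse: float | None
    msre: float | None
    undefined: Mapping[str, str] = dataclasses.field(default_factory=dict)


def error_measures(pairs, predicted=None) -> ErrorMeasures:
    """Compute MAE, MSE, RMSE and their relative/standardised variants.

    RMAE and RRMSE divide by the observed mean (flagged undefined when the
    mean is zero; reported as-is, hence negative, for a negative mean);
    SRMSE and MSRE standardise by the observed sample standard deviation
    and variance, making them unit- and variance-independent.
    """
    p = _as_pairs(pairs, predicted)
    err = p.observed - p.predicted
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    rmse = math.sqrt(mse)
    undefined: dict[str, str] = {}

    mean = p.mean_observed
    if mean == 0.0:
        rmae = rrmse = None
        undefined["rmae_pct"] = undefined["rrmse_pct"] = "observed mean is zero"
    else:
        rmae = mae / mean * 100.0
        rrmse = rmse / mean * 100.0

    s = p.s
    if s == 0.0:
        srmse = msre = None
        undefined["srmse"] = undefined["msre"] = "observed values have zero variance"
    else:
        srmse = rmse / s
        msre = mse / (s * s)
    return ErrorMeasures(mae, mse, rmse, rmae, rrmse, srmse, msre, undefined)


REPORT_FIELDS: Sequence[str] = (
    "n",
    "mean_observed",
    "s",
    "mae",
    "mse",
    "rmse",
    "rmae_pct",
    "rrmse_pct",
    "srmse",
    "msre",
    "vecv_pct",
    "e1_pct",
    "dr_pct",
    "r",
    "r2",
    "weighted_r",
)


@dataclass(frozen=True)
class MeasureReport:
    """All accuracy and error measures computed on one validation set.

    Measures that are mathematically undefined for the data are ``None``
    and carry a human-readable reason in :attr:`undefined` — they are
    marked, never silently dropped.
    """

    n: int
    mean_observed: float
    s: float
    mae: float
    mse: float
    rmse: float
    rmae_pct: float | None
    rrmse_pct: float | None
    srmse: float | None
    msre: float | None
    vecv_pct: float | None
    e1_pct: float | None
    dr_pct: float | None
    r: float | None
    r2: float | None
    weighted_r: float | None
    undefined: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flat mapping in fixed column order; undefined measures are None."""
        return {name: getattr(self, name) for name in REPORT_FIELDS}

    def to_json(self, **kwargs) -> str:
        payload = self.to_dict()
        payload["undefined"] = dict(self.undefined)
        return json.dumps(payload, **kwargs)


def full_report(pairs, predicted=None) -> MeasureReport:
    """Compute every measure on one validation set, marking undefined entries.

    Component-level :class:`UndefinedMeasureError` conditions do not abort
    the report: the affected entries are set to None with the reason kept.
    """
    p = _as_pairs(pairs, predicted)
    undefined: dict[str, str] = {}

    def attempt(name, fn):
        try:
            return fn(p)
        except UndefinedMeasureError as exc:
            undefined[name] = exc.reason
            return None

    errs = error_measures(p)
    undefined.update(errs.undefined)
    r_val = attempt("r", pearson_r)
    return MeasureReport(
        n=p.n,
        mean_observed=p.mean_observed,
        s=p.s,
        mae=errs.mae,
        mse=errs.mse,
        rmse=errs.rmse,
        rmae_pct=errs.rmae_pct,
        rrmse_pct=errs.rrmse_pct,
        srmse=errs.srmse,
        msre=errs.msre,
        vecv_pct=attempt("vecv_pct", vecv),
        e1_pct=attempt("e1_pct", e1),
        dr_pct=attempt("dr_pct", dr),
        r=r_val,
        r2=None if r_val is None else r_val * r_val,
        weighted_r=attempt("weighted_r", weighted_r),
        undefined=undefined,
    )
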