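"""Algebra linking VEcv to the MAE/MSE error-measure family.

Because ``VEcv = 100 * (1 - SSE / SS_tot)`` and ``MSE = SSE / n`` while
``SS_tot = (n - 1) * s^2``, every squared-error measure of a validation
set is an exact function of its VEcv and the summary statistics
``(n, s, mean)``::

    MSE   = s^2 * (1 - VEcv/100) * (n-1)/n
    RMSE  = sqrt(MSE)
    SRMSE = RMSE / s        = sqrt((1 - VEcv/100) * (n-1)/n)
    MSRE  = MSE / s^2       =      (1 - VEcv/100) * (n-1)/n
    RRMSE = 100 * RMSE/mean = 100 * SRMSE * CV

with ``CV = s / mean``.  These are identities, not approximations: they
hold for any dataset, so an error measure reported without its raw data
can be translated into the unit-free accuracy scale of VEcv (and back)
from ``(n, s, mean)`` alone.

MAE has no exact counterpart — the SSE does not determine the sum of
absolute errors — but across a large collection of real validation
exercises RMSE/MAE is close to a constant, empirically
``sqrt(2.0572)``.  The MAE/RMAE conversions here use

    MAE = s * sqrt((1 - VEcv/100) * (n-1) / (c * n)),   c = 2.0572,

and are flagged ``empirical``; ``c`` is exposed as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InputError, UndefinedMeasureError

__all__ = [
    "ConversionContext",
    "MAE_RATIO_CONSTANT",
    "vecv_to_mse",
    "vecv_to_error_report",
    "error_to_vecv",
    "CONVERTIBLE_MEASURES",
]

#: Empirical MSE/MAE^2 ratio used by the MAE and RMAE conversions.
MAE_RATIO_CONSTANT = 2.0572

CONVERTIBLE_MEASURES = ("mae", "mse", "rmse", "rmae", "rrmse", "srmse", "msre")

#: Conversions that are algebraic identities; the rest are empirical.
EXACT_MEASURES = frozenset({"mse", "rmse", "rrmse", "srmse", "msre"})


@dataclass(frozen=True)
class ConversionContext:
    """Summary statistics of a validation set sufficient for the conversions.

    Parameters
    ----------
    n : number of validation observations (>= 2).
    s : sample standard deviation (n-1 denominator) of the observed values; > 0.
    mean_observed : mean of the observed values; required (and non-zero) only
        for the relative measures RMAE/RRMSE.
    """

    n: int
    s: float
    mean_observed: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise InputError("conversion requires n >= 2")
        if not self.s > 0:
            raise InputError("conversion requires s > 0")

    @property
    def cv(self) -> float:
        """Coefficient of variation s/mean; sign follows the mean (not absolute-valued)."""
        if self.mean_observed is None or self.mean_observed == 0.0:
            raise UndefinedMeasureError("cv", "observed mean is zero or unknown")
        return self.s / self.mean_observed

    @classmethod
    def from_pairs(cls, pairs) -> "ConversionContext":
        return cls(n=pairs.n, s=pairs.s, mean_observed=pairs.mean_observed)


def _check_vecv(value: float) -> None:
    if value > 100.0:
        raise InputError(f"VEcv cannot exceed 100%; got {value}")


def vecv_to_mse(vecv: float, ctx: ConversionContext) -> float:
    """Exact MSE implied by a VEcv value and the validation set's (n, s)."""
    _check_vecv(vecv)
    return ctx.s**2 * (1.0 - vecv / 100.0) * (ctx.n - 1) / ctx.n


def vecv_to_error_report(
    vecv: float, ctx: ConversionContext, mae_constant: float = MAE_RATIO_CONSTANT
) -> dict:
    """Every convertible error measure implied by one VEcv value.

    Returns a dict with keys ``mae, mse, rmse, rmae_pct, rrmse_pct, srmse,
    msre`` plus ``exactness`` mapping each measure to ``"exact"`` or
    ``"empirical"``; relative measures are None when the observed mean is
    zero or unknown.
    """
    _check_vecv(vecv)
    mse = vecv_to_mse(vecv, ctx)
    rmse = math.sqrt(mse)
    reduced = (1.0 - vecv / 100.0) * (ctx.n - 1) / ctx.n  # = MSRE
    mae = ctx.s * math.sqrt(reduced / mae_constant)
    out = {
        "mae": mae,
        "mse": mse,
        "rmse": rmse,
        "srmse": math.sqrt(reduced),
        "msre": reduced,
        "exactness": {
            "mae": "empirical",
            "rmae_pct": "empirical",
            "mse": "exact",
            "rmse": "exact",
            "rrmse_pct": "exact",
            "srmse": "exact",
            "msre": "exact",
        },
    }
    if ctx.mean_observed in (None, 0.0):
        out["rmae_pct"] = None
        out["rrmse_pct"] = None
        out["undefined"] = {
            "rmae_pct": "observed mean is zero or unknown",
            "rrmse_pct": "observed mean is zero or unknown",
        }
    else:
        out["rmae_pct"] = mae / ctx.mean_observed * 100.0
        out["rrmse_pct"] = rmse / ctx.mean_observed * 100.0
        out["undefined"] = {}
    return out


def error_to_vecv(
    measure_name: str,
    value: float,
    ctx: ConversionContext,
    mae_constant: float = MAE_RATIO_CONSTANT,
) -> float:
    """VEcv (percent) implied by one error-measure value.

    Exact inverse for the MSE family (mse, rmse, rrmse, srmse, msre);
    empirical inverse for mae/rmae.  ``value`` is on the measure's native
    scale (percent for rmae/rrmse).
    """
    name = measure_name.lower()
    if name not in CONVERTIBLE_MEASURES:
        raise InputError(
            f"unknown measure {measure_name!r}; expected one of {CONVERTIBLE_MEASURES}"
        )
    if value < 0:
        raise InputError(f"error measures are non-negative; got {name}={value}")
    n, s = ctx.n, ctx.s
    scale = n / (n - 1)
    if name == "mse":
        reduced = value / s**2
    elif name == "rmse":
        reduced = (value / s) ** 2
    elif name == "srmse":
        reduced = value**2
    elif name == "msre":
        reduced = value
    elif name == "rrmse":
        reduced = (value / 100.0 / ctx.cv) ** 2
    elif name == "mae":
        reduced = mae_constant * (value / s) ** 2
    else:  # rmae
        reduced = mae_constant * (value / 100.0 / ctx.cv) ** 2
    return (1.0 - reduced * scale) * 100.0
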