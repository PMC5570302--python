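"""Naive loop-based reference implementations used only as test oracles.

Deliberately written with explicit Python loops and no shared code with
the package, so they stay independent of the vectorised implementations
they check.
"""

import math


def mean(v):
    return sum(v) / len(v)


def oracle_mae(obs, pred):
    return sum(abs(o - p) for o, p in zip(obs, pred)) / len(obs)


def oracle_mse(obs, pred):
    return sum((o - p) ** 2 for o, p in zip(obs, pred)) / len(obs)


def oracle_rmse(obs, pred):
    return math.sqrt(oracle_mse(obs, pred))


def oracle_sd(obs):
    m = mean(obs)
    return math.sqrt(sum((o - m) ** 2 for o in obs) / (len(obs) - 1))


def oracle_vecv(obs, pred):
    m = mean(obs)
    sse = sum((o - p) ** 2 for o, p in zip(obs, pred))
    ss = sum((o - m) ** 2 for o in obs)
    return (1 - sse / ss) * 100


def oracle_e1(obs, pred):
    m = mean(obs)
    sae = sum(abs(o - p) for o, p in zip(obs, pred))
    sad = sum(abs(o - m) for o in obs)
    return (1 - sae / sad) * 100


def oracle_dr(obs, pred):
    val = oracle_e1(obs, pred)
    if val >= 0:
        return val
    m = mean(obs)
    sae = sum(abs(o - p) for o, p in zip(obs, pred))
    sad = sum(abs(o - m) for o in obs)
    return (sad / sae - 1) * 100


def oracle_r(obs, pred):
    mo, mp = mean(obs), mean(pred)
    num = sum((o - mo) * (p - mp) for o, p in zip(obs, pred))
    den = math.sqrt(
        sum((o - mo) ** 2 for o in obs) * sum((p - mp) ** 2 for p in pred)
    )
    return num / den


def oracle_slope(obs, pred):
    mo, mp = mean(obs), mean(pred)
    num = sum((o - mo) * (p - mp) for o, p in zip(obs, pred))
    den = sum((o - mo) ** 2 for o in obs)
    return num / den


def oracle_weighted_r(obs, pred):
    r = oracle_r(obs, pred)
    b = abs(oracle_slope(obs, pred))
    return r * (b if b <= 1 else 1 / b)


ORACLES = {
    "mae": oracle_mae,
    "mse": oracle_mse,
    "rmse": oracle_rmse,
    "vecv_pct": oracle_vecv,
    "e1_pct": oracle_e1,
    "dr_pct": oracle_dr,
    "r": oracle_r,
    "weighted_r": oracle_weighted_r,
}
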