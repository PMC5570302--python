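"""Unit and property tests for the accuracy/error measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import vecv
from vecv import PairedData, full_report
from vecv.exceptions import InputError, UndefinedMeasureError

from _oracles import ORACLES


class TestPairedData:
    def test_rejects_length_mismatch(self):
        with pytest.raises(InputError, match="length mismatch"):
            PairedData(np.arange(3.0), np.arange(4.0))

    def test_rejects_singletons(self):
        with pytest.raises(InputError):
            PairedData(np.array([1.0]), np.array([1.0]))

    def test_rejects_missing_values(self):
        with pytest.raises(InputError, match="row"):
            PairedData(np.array([1.0, np.nan, 3.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InputError):
            PairedData(np.array([1.0, 2.0]), np.array([np.inf, 2.0]))

    def test_sample_sd_uses_n_minus_1(self, x30):
        p = PairedData(x30, x30)
        assert p.s == pytest.approx(math.sqrt(2247.5 / 29), rel=1e-14)


class TestExamples:
    """Worked examples with hand- or oracle-derived expected values."""

    def test_vecv_slope_09(self, x30):
        assert vecv.vecv(x30, 0.9 * x30) == pytest.approx(95.79, abs=5e-3)

    def test_vecv_perfect_and_mean(self, x30):
        assert vecv.vecv(x30, x30) == pytest.approx(100.0, abs=1e-12)
        assert vecv.vecv(x30, np.full(30, 15.5)) == pytest.approx(0.0, abs=1e-12)

    def test_e1_slope_09(self, x30):
        # sum|0.1 x| = 46.5, sum|x - 15.5| = 225 -> 1 - 46.5/225
        assert vecv.e1(x30, 0.9 * x30) == pytest.approx((1 - 46.5 / 225) * 100, rel=1e-12)

    def test_e1_negative_hand_case(self):
        obs, pred = np.array([1.0, 2, 3]), np.array([3.0, 3, 3])
        assert vecv.e1(obs, pred) == pytest.approx(-50.0, rel=1e-12)
        assert vecv.dr(obs, pred) == pytest.approx((2 / 3 - 1) * 100, rel=1e-12)

    def test_dr_positive_branch_equals_e1(self, x30):
        assert vecv.dr(x30, 0.9 * x30) == vecv.e1(x30, 0.9 * x30)

    def test_pearson_examples(self, x30):
        assert vecv.pearson_r(x30, 0.6 * x30) == pytest.approx(1.0, abs=1e-12)
        assert vecv.pearson_r(x30, -x30) == pytest.approx(-1.0, abs=1e-12)
        obs, pred = np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3])
        assert vecv.pearson_r(obs, pred) == pytest.approx(0.6, rel=1e-12)

    def test_weighted_r_damps_both_directions(self, x30):
        assert vecv.weighted_r(x30, x30) == pytest.approx(1.0, abs=1e-12)
        assert vecv.weighted_r(x30, 0.5 * x30) == pytest.approx(0.5, rel=1e-12)
        assert vecv.weighted_r(x30, 2.0 * x30) == pytest.approx(0.5, rel=1e-12)

    def test_error_measures_slope_09(self, x30):
        em = vecv.error_measures(x30, 0.9 * x30)
        assert em.mae == pytest.approx(1.55, rel=1e-12)  # 46.5/30
        assert em.mse == pytest.approx(94.55 / 30, rel=1e-12)  # 0.01*9455/30
        assert em.srmse == pytest.approx(em.rmse / math.sqrt(2247.5 / 29), rel=1e-12)

    def test_error_measures_zero_for_perfect(self, x30):
        em = vecv.error_measures(x30, x30)
        for name in ("mae", "mse", "rmse", "rmae_pct", "rrmse_pct", "srmse", "msre"):
            assert getattr(em, name) == 0.0


class TestUndefinedHandling:
    def test_constant_observed_rejected_by_variance_measures(self):
        obs = np.full(5, 7.0)
        pred = np.arange(5.0)
        for fn in (vecv.vecv, vecv.e1, vecv.dr, vecv.pearson_r):
            with pytest.raises(UndefinedMeasureError):
                fn(obs, pred)

    def test_constant_prediction_r_marked_not_zero(self, x30):
        with pytest.raises(UndefinedMeasureError, match="constant"):
            vecv.pearson_r(x30, np.full(30, 3.0))

    def test_zero_mean_flags_relative_errors_only(self):
        obs = np.array([-2.0, -1, 1, 2])
        em = vecv.error_measures(obs, obs * 0.5)
        assert em.rmae_pct is None and em.rrmse_pct is None
        assert "rmae_pct" in em.undefined
        assert em.mae > 0 and em.srmse is not None

    def test_full_report_marks_instead_of_dropping(self, x30):
        rep = full_report(x30, np.full(30, 3.0))
        assert rep.r is None and rep.r2 is None
        assert "r" in rep.undefined
        assert rep.vecv_pct is not None  # other measures survive


class TestFullReport:
    def test_agrees_with_component_measures(self, x30):
        rep = full_report(x30, 0.9 * x30)
        assert rep.vecv_pct == vecv.vecv(x30, 0.9 * x30)
        assert rep.e1_pct == vecv.e1(x30, 0.9 * x30)
        assert rep.dr_pct == vecv.dr(x30, 0.9 * x30)
        assert rep.r == vecv.pearson_r(x30, 0.9 * x30)
        assert rep.mae == vecv.error_measures(x30, 0.9 * x30).mae

    def test_negative_e1_and_dr_coexist(self):
        rep = full_report(np.array([1.0, 2, 3]), np.array([3.0, 3, 3]))
        assert rep.e1_pct == pytest.approx(-50.0)
        assert rep.dr_pct == pytest.approx(-100 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_internal_consistency(self, random_pairs, seed):
        rep = full_report(random_pairs(seed))
        assert rep.rmse == pytest.approx(math.sqrt(rep.mse), rel=1e-12)
        assert rep.srmse == pytest.approx(rep.rmse / rep.s, rel=1e-12)
        assert rep.msre == pytest.approx(rep.mse / rep.s**2, rel=1e-12)
        assert rep.r2 == pytest.approx(rep.r**2, rel=1e-12)
        assert rep.vecv_pct <= 100 and rep.e1_pct <= 100
        if rep.e1_pct >= 0:
            assert rep.dr_pct == rep.e1_pct
        else:
            assert -100 < rep.dr_pct < 0
        assert abs(rep.weighted_r) <= abs(rep.r) + 1e-15


@pytest.mark.parametrize("seed", range(40))
def test_oracle_equivalence(random_pairs, seed):
    """Every measure matches an independent loop-based oracle to 1e-12."""
    p = random_pairs(seed)
    rep = full_report(p)
    obs, pred = p.observed.tolist(), p.predicted.tolist()
    for name, oracle in ORACLES.items():
        expected = oracle(obs, pred)
        assert getattr(rep, name) == pytest.approx(expected, rel=1e-12, abs=1e-12), name


@pytest.mark.parametrize("seed", range(5))
def test_pearson_matches_scipy(random_pairs, seed):
    p = random_pairs(seed)
    assert vecv.pearson_r(p) == pytest.approx(
        stats.pearsonr(p.observed, p.predicted).statistic, rel=1e-12
    )


finite = dict(allow_nan=False, allow_infinity=False)


@given(
    a=st.floats(min_value=-50, max_value=50, **finite),
    b=st.floats(min_value=0.01, max_value=50, **finite),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_r_is_affine_blind_but_vecv_is_not(a, b, seed):
    """r = 1 for any positive affine transform of the observations; VEcv < 100
    unless the transform is the identity."""
    rng = np.random.default_rng(seed)
    obs = rng.normal(0, 3, size=20) + np.linspace(0, 10, 20)  # guaranteed variance
    pred = a + b * obs
    assert vecv.pearson_r(obs, pred) == pytest.approx(1.0, abs=1e-9)
    v = vecv.vecv(obs, pred)
    assert v <= 100 + 1e-12
    if abs(a) > 1e-6 or abs(b - 1) > 1e-6:
        assert v < 100


@given(
    c=st.floats(min_value=0.01, max_value=100, **finite),
    shift=st.floats(min_value=-100, max_value=100, **finite),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_unit_invariance(c, shift, seed):
    """vecv/e1/dr/r are invariant under a common unit change; mae/rmse scale
    by the factor; srmse/msre are scale-invariant."""
    rng = np.random.default_rng(seed)
    obs = rng.normal(5, 2, size=25)
    pred = obs * 0.8 + rng.normal(0, 1, size=25)
    r1, r2 = full_report(obs, pred), full_report(c * obs + shift, c * pred + shift)
    for name in ("vecv_pct", "e1_pct", "dr_pct", "r"):
        assert getattr(r2, name) == pytest.approx(getattr(r1, name), rel=1e-8, abs=1e-8)
    assert r2.mae == pytest.approx(c * r1.mae, rel=1e-8)
    assert r2.rmse == pytest.approx(c * r1.rmse, rel=1e-8)
    if shift == 0:
        assert r2.srmse == pytest.approx(r1.srmse, rel=1e-8)
        assert r2.msre == pytest.approx(r1.msre, rel=1e-8)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_dr_equals_e1_iff_nonnegative(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 60))
    obs = rng.normal(0, rng.uniform(0.5, 10), size=n) + np.linspace(0, 5, n)
    p = PairedData(obs, rng.uniform(0.2, 1.8) * obs + rng.normal(0, 5, size=n))
    e1_val, dr_val = vecv.e1(p), vecv.dr(p)
    if e1_val >= 0:
        assert dr_val == e1_val
    else:
        assert -100 < dr_val < 0
        assert dr_val > e1_val


def test_perfect_prediction_is_the_unique_100():
    rng = np.random.default_rng(0)
    obs = rng.normal(size=15)
    assert vecv.vecv(obs, obs) == pytest.approx(100, abs=1e-12)
    assert vecv.e1(obs, obs) == pytest.approx(100, abs=1e-12)
    assert vecv.dr(obs, obs) == pytest.approx(100, abs=1e-12)
    pred = obs.copy()
    pred[0] += 0.5
    assert vecv.vecv(obs, pred) < 100
    assert vecv.e1(obs, pred) < 100
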