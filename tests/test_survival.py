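"""Weibull parameterization, curve evaluation, and censored fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gistcea.defaults import WEIBULL_AFT, WEIBULL_SHAPE_RATE
from gistcea.survival import (
    IPDRecord,
    WeibullAFT,
    WeibullSR,
    aft_to_shape_rate,
    fit_weibull_aft,
    make_hybrid_curve,
    median_survival,
    per_cycle_exit_prob,
    restricted_mean,
    survival_at,
)
from gistcea.synthetic import SimSpec, simulate_ipd

RIP_OS = WeibullSR(shape=1.535033646, rate=0.013971806)
PLA_OS = WeibullSR(shape=0.999014696, rate=0.105568583)


@pytest.mark.parametrize("key", sorted(WEIBULL_AFT))
def test_aft_mapping_reproduces_published_shape_rate(key):
    sr = aft_to_shape_rate(WEIBULL_AFT[key])
    shape, rate = WEIBULL_SHAPE_RATE[key]
    assert sr.shape == pytest.approx(shape, rel=1e-3)
    assert sr.rate == pytest.approx(rate, rel=1e-3)


def test_aft_mapping_identity_case():
    sr = aft_to_shape_rate(WeibullAFT(0.0, 0.0))
    assert (sr.shape, sr.rate) == (1.0, 1.0)


def test_aft_round_trip():
    sr = RIP_OS.to_aft().to_shape_rate()
    assert sr.shape == pytest.approx(RIP_OS.shape, rel=1e-12)
    assert sr.rate == pytest.approx(RIP_OS.rate, rel=1e-12)


def test_survival_at_origin_and_examples():
    for curve in (RIP_OS, PLA_OS):
        assert survival_at(curve, 0.0) == 1.0
    assert survival_at(RIP_OS, 12.0) == pytest.approx(0.5306648324577302, abs=1e-9)
    t_med = (math.log(2.0) / PLA_OS.rate) ** (1.0 / PLA_OS.shape)
    assert survival_at(PLA_OS, t_med) == pytest.approx(0.5, abs=1e-12)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        survival_at(RIP_OS, -1.0)


@settings(max_examples=50, deadline=None)
@given(
    shape=st.floats(0.3, 4.0),
    rate=st.floats(1e-3, 1.0),
)
def test_survival_nonincreasing_on_grid(shape, rate):
    curve = WeibullSR(shape=shape, rate=rate)
    t = np.linspace(0.0, 120.0, 500)
    s = curve.survival(t)
    assert s[0] == 1.0
    assert np.all(np.diff(s) <= 1e-15)
    assert np.all((s >= 0) & (s <= 1))


def test_median_examples():
    assert round(median_survival(PLA_OS), 1) == 6.6
    assert median_survival(WeibullSR(1.0, math.log(2.0))) == pytest.approx(1.0)
    rip_pfs = WeibullSR(1.096622663, 0.102752314)
    assert median_survival(rip_pfs) == pytest.approx(5.701488489807756, rel=1e-9)


@pytest.mark.parametrize("key", sorted(WEIBULL_SHAPE_RATE))
def test_median_inverts_survival(key):
    curve = WeibullSR(*WEIBULL_SHAPE_RATE[key])
    m = median_survival(curve)
    assert abs(survival_at(curve, m) - 0.5) < 1e-6


def test_median_requires_crossing():
    slow = WeibullSR(shape=1.0, rate=1e-9)
    with pytest.raises(ValueError):
        median_survival(slow, horizon=100.0)


def test_restricted_mean_exponential_closed_form():
    lam = 0.25
    assert restricted_mean(WeibullSR(1.0, lam), horizon=400.0) == pytest.approx(
        1.0 / lam, rel=1e-4
    )


@pytest.mark.parametrize(
    "key, expected",
    [(("placebo", "pfs"), 2.0355486846374413), (("placebo", "os"), 9.497506533633777)],
)
def test_restricted_mean_matches_gamma_closed_form(key, expected):
    curve = WeibullSR(*WEIBULL_SHAPE_RATE[key])
    assert restricted_mean(curve, horizon=240.0, annual_discount=0.0) == pytest.approx(
        expected, rel=5e-3
    )


def test_restricted_mean_all_curves_within_half_percent():
    for shape, rate in WEIBULL_SHAPE_RATE.values():
        curve = WeibullSR(shape, rate)
        closed = rate ** (-1.0 / shape) * math.gamma(1.0 + 1.0 / shape)
        assert restricted_mean(curve, 240.0) == pytest.approx(closed, rel=5e-3)


def test_discounting_shrinks_restricted_mean():
    assert restricted_mean(PLA_OS, 240.0, annual_discount=0.03) < restricted_mean(
        PLA_OS, 240.0, annual_discount=0.0
    )


def test_per_cycle_exit_memoryless_and_examples():
    lam = 0.3
    expo = WeibullSR(1.0, lam)
    probs = [per_cycle_exit_prob(expo, k, 1.0) for k in range(1, 6)]
    assert np.allclose(probs, 1.0 - math.exp(-lam))
    assert per_cycle_exit_prob(RIP_OS, 1, 1.0) == pytest.approx(
        0.013874653311046203, rel=1e-9
    )
    increasing = [per_cycle_exit_prob(RIP_OS, k, 1.0) for k in range(1, 40)]
    assert np.all(np.diff(increasing) > 0)  # shape > 1: rising hazard


def test_per_cycle_exit_exhausted_cohort():
    fast = WeibullSR(1.0, 5.0)
    with pytest.raises(ValueError):
        per_cycle_exit_prob(fast, 200, 1.0)


class TestHybridCurve:
    def test_continuous_at_junction(self):
        km = [(0.0, 1.0), (1.0, 0.9), (2.0, 0.7), (3.0, 0.55)]
        hybrid = make_hybrid_curve(km, tail=PLA_OS, junction=3.0)
        assert survival_at(hybrid, 3.0) == pytest.approx(0.55)
        assert survival_at(hybrid, 3.0 + 1e-9) == pytest.approx(0.55, rel=1e-6)

    def test_empty_table_is_pure_tail(self):
        hybrid = make_hybrid_curve([], tail=RIP_OS, junction=0.0)
        t = np.linspace(0, 60, 200)
        assert np.allclose(hybrid.survival(t), RIP_OS.survival(t))

    def test_proportional_tail_identity(self):
        km = [(0.0, 1.0), (2.0, 0.8), (4.0, 0.6)]
        j = 4.0
        hybrid = make_hybrid_curve(km, tail=RIP_OS, junction=j)
        ratio = survival_at(hybrid, 2 * j) / survival_at(hybrid, j)
        pure = survival_at(RIP_OS, 2 * j) / survival_at(RIP_OS, j)
        assert ratio == pytest.approx(pure, rel=1e-12)

    def test_junction_beyond_table_rejected(self):
        with pytest.raises(ValueError):
            make_hybrid_curve([(0.0, 1.0), (1.0, 0.9)], tail=RIP_OS, junction=5.0)

    def test_invalid_step_function_rejected(self):
        with pytest.raises(ValueError):
            make_hybrid_curve([(0.0, 1.0), (1.0, 1.1)], tail=RIP_OS, junction=1.0)
        with pytest.raises(ValueError):
            make_hybrid_curve([(1.0, 0.9)], tail=RIP_OS, junction=1.0)

    def test_median_by_bisection_matches_tail(self):
        hybrid = make_hybrid_curve([], tail=PLA_OS, junction=0.0)
        assert median_survival(hybrid) == pytest.approx(PLA_OS.median(), abs=1e-6)


class TestFitWeibullAFT:
    def test_recovers_truth_without_censoring(self):
        data = simulate_ipd(
            SimSpec(n=5000, curve=PLA_OS, admin_censor_time=1e9, seed=42)
        )
        fit = fit_weibull_aft(data)
        sr = fit.to_shape_rate()
        assert sr.shape == pytest.approx(PLA_OS.shape, rel=0.05)
        assert sr.rate == pytest.approx(PLA_OS.rate, rel=0.05)
        assert fit.se_intercept > 0 and fit.se_log_scale > 0

    def test_all_censored_rejected(self):
        data = [IPDRecord(time=5.0, event=False) for _ in range(20)]
        with pytest.raises(ValueError):
            fit_weibull_aft(data)

    def test_exponential_closed_form_oracle(self):
        # for shape = 1 the rate MLE is (number of events) / (total follow-up)
        expo = WeibullSR(1.0, 0.15)
        data = simulate_ipd(
            SimSpec(n=4000, curve=expo, admin_censor_time=12.0, seed=7)
        )
        events = sum(r.event for r in data)
        total_time = sum(r.time for r in data)
        fit = fit_weibull_aft(data)
        assert fit.to_shape_rate().rate == pytest.approx(
            events / total_time, rel=0.05
        )

    def test_matches_lifelines_mle(self):
        from lifelines import WeibullFitter

        data = simulate_ipd(
            SimSpec(n=1500, curve=RIP_OS, admin_censor_time=24.0, seed=3)
        )
        fit = fit_weibull_aft(data).to_shape_rate()
        wf = WeibullFitter().fit(
            [r.time for r in data], [r.event for r in data]
        )
        # lifelines parameterizes S(t) = exp(-(t/lambda_)^rho_)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.rate == pytest.approx(wf.lambda_**-wf.rho_, rel=1e-3)

    def test_mean_bias_small_over_replicates(self):
        # administrative censoring at S(c) = 0.2 leaves ~20% censored
        truth = PLA_OS
        c = (math.log(5.0) / truth.rate) ** (1.0 / truth.shape)
        shapes, rates = [], []
        for seed in range(20):
            data = simulate_ipd(
                SimSpec(n=2000, curve=truth, admin_censor_time=c, seed=100 + seed)
            )
            sr = fit_weibull_aft(data).to_shape_rate()
            shapes.append(sr.shape)
            rates.append(sr.rate)
        assert abs(np.mean(shapes) / truth.shape - 1.0) < 0.02
        assert abs(np.mean(rates) / truth.rate - 1.0) < 0.02
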