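"""Tornado, price sweep, threshold inversion, PSA and acceptability curve."""

import numpy as np
import pandas as pd
import pytest

from gistcea.defaults import PUBLISHED_PRICE_SWEEP
from gistcea.sensitivity import (
    ParamSpec,
    ceac,
    default_one_way_specs,
    default_psa_specs,
    one_way_sweep,
    price_sweep,
    psa_run,
    threshold_price,
)


class TestOneWay:
    def test_placebo_os_shape_low_bound_value(self, calibrated_model):
        specs = {s.name: s for s in default_one_way_specs(calibrated_model)}
        # the ±10% convention puts the low bound at 0.9 x 0.999014696
        assert specs["os_placebo_shape"].low == pytest.approx(0.89911, abs=5e-6)

    def test_lowering_placebo_os_shape_lowers_icer(self, calibrated_model):
        base = calibrated_model.evaluate()
        perturbed = calibrated_model.evaluate(
            {"os_placebo_shape": 0.9 * 0.999014696}
        )
        # longer placebo survival inflates crossover drug cost: the
        # comparison moves strictly in ripretinib's favour, up to dominance
        assert perturbed.status == "dominant" or perturbed.icer < base.icer

    def test_zero_width_row_for_degenerate_bounds(self, calibrated_model):
        spec = ParamSpec("utility_pf", base=0.767, low=0.767, high=0.767)
        df = one_way_sweep([spec], calibrated_model)
        assert df.loc[0, "width"] == 0.0

    def test_rows_sorted_by_width_with_flags_last(self, calibrated_model):
        specs = default_one_way_specs(calibrated_model)
        df = one_way_sweep(specs, calibrated_model)
        widths = df["width"].to_numpy()
        finite = widths[~np.isnan(widths)]
        assert np.all(np.diff(finite) <= 1e-9)
        if np.isnan(widths).any():
            assert np.isnan(widths[-1])  # flagged rows excluded from ordering


class TestPriceSweep:
    def test_identity_row_matches_base_case(self, calibrated_model):
        df = price_sweep([32_000.0], calibrated_model)
        assert df.loc[0, "icer"] == pytest.approx(244_010.0, abs=0.5)

    def test_all_published_rows_within_half_percent(self, calibrated_model):
        rows = PUBLISHED_PRICE_SWEEP.rows
        df = price_sweep(sorted(rows), calibrated_model).set_index("price")
        for price, (total, d_cost, icer) in rows.items():
            got = df.loc[price]
            assert got["total_cost"] == pytest.approx(total, rel=5e-3)
            assert got["incremental_cost"] == pytest.approx(d_cost, rel=5e-3)
            assert got["icer"] == pytest.approx(icer, rel=5e-3)

    def test_incremental_qalys_constant_across_prices(self, calibrated_model):
        df = price_sweep([3_200.0, 16_000.0, 32_000.0], calibrated_model)
        assert df["incremental_qaly"].nunique() == 1

    def test_negative_price_rejected(self, calibrated_model):
        with pytest.raises(ValueError):
            price_sweep([-1.0], calibrated_model)


class TestThreshold:
    def test_published_threshold_at_150k(self, calibrated_model):
        assert threshold_price(150_000.0, calibrated_model) == pytest.approx(
            14_057.0, abs=25.0
        )

    def test_base_icer_is_fixed_point(self, calibrated_model):
        base_icer = calibrated_model.icer()
        assert threshold_price(base_icer, calibrated_model) == pytest.approx(
            32_000.0, abs=1.0
        )

    @pytest.mark.parametrize("wtp", [100_000.0, 150_000.0, 200_000.0, 244_010.0])
    def test_round_trip_icer_within_dollar(self, calibrated_model, wtp):
        price = threshold_price(wtp, calibrated_model)
        icer = calibrated_model.icer({"drug_cost_monthly": price})
        assert icer == pytest.approx(wtp, abs=1.0)

    def test_unreachable_wtp_raises(self, calibrated_model):
        # even a free drug leaves the ICER near $76k/QALY
        with pytest.raises(ValueError):
            threshold_price(50_000.0, calibrated_model)


class TestPSA:
    def test_zero_dispersion_returns_base_case(self, calibrated_model):
        base = calibrated_model.evaluate()
        specs = [
            ParamSpec("drug_cost_monthly", 32_000.0, 0.0, np.inf, "gamma", 0.0),
            ParamSpec("utility_pf", 0.767, 0.0, 1.0, "beta", 0.0),
        ]
        samples = psa_run(specs, 5, seed=1, model=calibrated_model)
        assert np.allclose(samples["delta_cost"], base.incremental_cost)
        assert np.allclose(samples["delta_qaly"], base.incremental_qaly)

    def test_same_seed_is_bit_reproducible(self, calibrated_model):
        specs = default_psa_specs(calibrated_model)
        a = psa_run(specs, 40, seed=11, model=calibrated_model)
        b = psa_run(specs, 40, seed=11, model=calibrated_model)
        pd.testing.assert_frame_equal(a, b)

    def test_adding_parameter_preserves_other_streams(self, calibrated_model):
        specs = default_psa_specs(calibrated_model)
        a = psa_run(specs, 30, seed=5, model=calibrated_model)
        b = psa_run(specs[:-1], 30, seed=5, model=calibrated_model)
        shared = [s.name for s in specs[:-1]]
        pd.testing.assert_frame_equal(a[shared], b[shared])

    def test_gamma_cost_means_match_base_at_10k_draws(self, calibrated_model):
        specs = [
            s for s in default_psa_specs(calibrated_model) if s.distribution == "gamma"
        ]
        samples = psa_run(specs, 10_000, seed=2021, model=calibrated_model)
        for spec in specs:
            assert samples[spec.name].mean() == pytest.approx(spec.base, rel=0.02)

    def test_beta_moment_matching_infeasibility_detected(self):
        spec = ParamSpec("utility_pf", 0.767, 0.0, 1.0, "beta", 0.6)
        with pytest.raises(ValueError, match="infeasible"):
            spec.sample(np.random.default_rng(0), 10)

    def test_small_dispersion_converges_to_base(self, calibrated_model):
        base = calibrated_model.evaluate()
        specs = default_psa_specs(
            calibrated_model, cost_cv=1e-6, utility_cv=1e-6, survival_se=1e-6
        )
        samples = psa_run(specs, 20, seed=3, model=calibrated_model)
        assert np.allclose(samples["delta_cost"], base.incremental_cost, rtol=1e-3)
        assert np.allclose(samples["delta_qaly"], base.incremental_qaly, rtol=1e-3)


class TestCEAC:
    def test_degenerate_psa_steps_at_base_icer(self, calibrated_model):
        base = calibrated_model.evaluate()
        samples = pd.DataFrame(
            {
                "delta_cost": [base.incremental_cost] * 4,
                "delta_qaly": [base.incremental_qaly] * 4,
            }
        )
        curve = ceac(samples, [0.0, 200_000.0, 244_010.0, 300_000.0])
        assert list(curve["prob_cost_effective"]) == [0.0, 0.0, 1.0, 1.0]

    def test_monotone_when_all_gains_positive(self, calibrated_model):
        specs = default_psa_specs(calibrated_model)
        samples = psa_run(specs, 400, seed=9, model=calibrated_model)
        gains = samples[samples["delta_qaly"] > 0]
        curve = ceac(gains, np.arange(0.0, 400_001.0, 10_000.0))
        assert np.all(np.diff(curve["prob_cost_effective"]) >= -1e-12)
        assert curve["prob_cost_effective"].between(0.0, 1.0).all()

    def test_ceac_at_zero_is_cost_saving_fraction(self, calibrated_model):
        specs = default_psa_specs(calibrated_model)
        samples = psa_run(specs, 300, seed=13, model=calibrated_model)
        curve = ceac(samples, [0.0])
        frac = float((samples["delta_cost"] <= 0.0).mean())
        assert curve.loc[0, "prob_cost_effective"] == pytest.approx(frac)

    def test_very_large_wtp_reaches_one_for_positive_gains(self, calibrated_model):
        specs = default_psa_specs(calibrated_model)
        samples = psa_run(specs, 200, seed=17, model=calibrated_model)
        gains = samples[samples["delta_qaly"] > 0]
        curve = ceac(gains, [1e12])
        assert curve.loc[0, "prob_cost_effective"] == 1.0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame(columns=["delta_cost", "delta_qaly"]), [0.0])
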