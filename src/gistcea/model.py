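"""End-to-end cost-effectiveness model with named-parameter overrides.

:class:`CostEffectivenessModel` wraps the survival curves, the cohort
engine and the economics layer behind a single ``evaluate`` call that the
sensitivity machinery can drive by parameter name.  Two evaluation modes:

raw
    Discounted state times come straight from the cohort trace built from
    the (possibly perturbed) Weibull curves.

calibrated (default when a fixture is supplied)
    The base-case state times are the calibrated occupancy fixture; a
    perturbation of the survival parameters shifts each state time by the
    change it induces in the raw trace (the fixture plus the raw delta,
    clamped at zero).  Incremental QALYs are the fixture's unrounded value
    scaled by the relative change in the state-time/utility QALY difference,
    so utility rescaling propagates exactly and the unperturbed model
    reproduces the published base case.

Recognized parameter names
--------------------------
``drug_cost_monthly``, ``bsc_cost_monthly``, ``ae_onetime_cost``,
``ct_cost_per_cycle``, ``utility_pf``, ``utility_pd``,
``crossover_fraction``, and per-curve survival parameters
``{os|pfs}_{arm}_{shape|rate|intercept|log_scale}`` (e.g.
``os_placebo_shape``).  Shape/rate and intercept/log_scale overrides for the
same curve are mutually exclusive within one evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .cohort import ModelConfig, build_trace, state_time
from .defaults import (
    AE_ONETIME_COST,
    BSC_COST_MONTHLY,
    CROSSOVER_FRACTION,
    CT_COST_PER_CYCLE,
    DRUG_COST_MONTHLY,
    WEIBULL_AFT,
)
from .economics import (
    ArmResult,
    ArmSpec,
    CEResult,
    StateTimeFixture,
    accrue_costs,
    accrue_qalys,
    compare,
)
from .survival import SurvivalCurve, WeibullAFT, WeibullSR

__all__ = [
    "CostEffectivenessModel",
    "default_arms",
    "default_curves",
    "default_model",
]

_COST_UTILITY_PARAMS = (
    "drug_cost_monthly",
    "bsc_cost_monthly",
    "ae_onetime_cost",
    "ct_cost_per_cycle",
    "utility_pf",
    "utility_pd",
    "crossover_fraction",
)


def default_arms() -> tuple[ArmSpec, ArmSpec]:
    """The two published strategies: ripretinib + BSC versus BSC alone."""
    intervention = ArmSpec(
        name="ripretinib",
        drug_cost_monthly=DRUG_COST_MONTHLY,
        bsc_cost_monthly=BSC_COST_MONTHLY,
        ae_onetime_cost=AE_ONETIME_COST,
        ct_cost_per_cycle=CT_COST_PER_CYCLE,
        crossover_fraction=0.0,
    )
    comparator = ArmSpec(
        name="placebo",
        drug_cost_monthly=0.0,
        bsc_cost_monthly=BSC_COST_MONTHLY,
        ae_onetime_cost=AE_ONETIME_COST,
        ct_cost_per_cycle=CT_COST_PER_CYCLE,
        crossover_fraction=CROSSOVER_FRACTION,
    )
    return intervention, comparator


def default_curves() -> dict[tuple[str, str], SurvivalCurve]:
    """Published Weibull OS/PFS curves keyed by (arm name, endpoint)."""
    return {k: v.to_shape_rate() for k, v in WEIBULL_AFT.items()}


@dataclass
class CostEffectivenessModel:
    """Two-strategy three-state cost-effectiveness model."""

    intervention: ArmSpec
    comparator: ArmSpec
    curves: Mapping[tuple[str, str], SurvivalCurve]
    config: ModelConfig = field(default_factory=ModelConfig)
    fixture: StateTimeFixture | None = None

    def __post_init__(self) -> None:
        self._base_raw_times: dict[str, tuple[float, float]] | None = None

    # -- parameters --------------------------------------------------------

    def base_parameters(self) -> dict[str, float]:
        """Base value of every recognized scalar parameter."""
        out = {
            "drug_cost_monthly": self.intervention.drug_cost_monthly,
            "bsc_cost_monthly": self.intervention.bsc_cost_monthly,
            "ae_onetime_cost": self.intervention.ae_onetime_cost,
            "ct_cost_per_cycle": self.intervention.ct_cost_per_cycle,
            "utility_pf": self.config.utility_pf,
            "utility_pd": self.config.utility_pd,
            "crossover_fraction": self.comparator.crossover_fraction,
        }
        for (arm, endpoint), curve in self.curves.items():
            if isinstance(curve, WeibullAFT):
                curve = curve.to_shape_rate()
            if isinstance(curve, WeibullSR):
                out[f"{endpoint}_{arm}_shape"] = curve.shape
                out[f"{endpoint}_{arm}_rate"] = curve.rate
                aft = curve.to_aft()
                out[f"{endpoint}_{arm}_intercept"] = aft.intercept
                out[f"{endpoint}_{arm}_log_scale"] = aft.log_scale
        return out

    def _resolve_curves(
        self, overrides: Mapping[str, float]
    ) -> dict[tuple[str, str], SurvivalCurve]:
        curves = dict(self.curves)
        by_curve: dict[tuple[str, str], dict[str, float]] = {}
        for name, value in overrides.items():
            if name in _COST_UTILITY_PARAMS:
                continue
            parts = name.split("_", 2)
            if len(parts) != 3 or parts[0] not in ("os", "pfs"):
                raise KeyError(f"unrecognized parameter {name!r}")
            endpoint, arm, param = parts
            if (arm, endpoint) not in curves:
                raise KeyError(f"no curve for arm {arm!r}, endpoint {endpoint!r}")
            if param not in ("shape", "rate", "intercept", "log_scale"):
                raise KeyError(f"unrecognized survival parameter {param!r}")
            by_curve.setdefault((arm, endpoint), {})[param] = value
        for key, params in by_curve.items():
            base = curves[key]
            if isinstance(base, WeibullAFT):
                base = base.to_shape_rate()
            if not isinstance(base, WeibullSR):
                raise TypeError(
                    f"survival-parameter overrides need a Weibull curve at {key}"
                )
            sr_keys = {"shape", "rate"} & params.keys()
            aft_keys = {"intercept", "log_scale"} & params.keys()
            if sr_keys and aft_keys:
                raise ValueError(
                    f"mixed shape/rate and AFT overrides for curve {key}"
                )
            if aft_keys:
                aft = base.to_aft()
                aft = WeibullAFT(
                    intercept=params.get("intercept", aft.intercept),
                    log_scale=params.get("log_scale", aft.log_scale),
                )
                curves[key] = aft.to_shape_rate()
            else:
                curves[key] = WeibullSR(
                    shape=params.get("shape", base.shape),
                    rate=params.get("rate", base.rate),
                )
        return curves

    # -- evaluation --------------------------------------------------------

    def _raw_state_times(
        self, curves: Mapping[tuple[str, str], SurvivalCurve]
    ) -> dict[str, tuple[float, float]]:
        out = {}
        for arm in (self.intervention.name, self.comparator.name):
            trace = build_trace(
                curves[(arm, "os")], curves[(arm, "pfs")], self.config
            )
            out[arm] = (
                state_time(trace, "pf", self.config, discounted=True),
                state_time(trace, "pd", self.config, discounted=True),
            )
        return out

    def base_raw_state_times(self) -> dict[str, tuple[float, float]]:
        if self._base_raw_times is None:
            self._base_raw_times = self._raw_state_times(dict(self.curves))
        return self._base_raw_times

    def state_times(
        self, overrides: Mapping[str, float] | None = None
    ) -> dict[str, tuple[float, float]]:
        """Discounted (pf, pd) months per arm under the active mode."""
        overrides = dict(overrides or {})
        curves = self._resolve_curves(overrides)
        raw = self._raw_state_times(curves)
        if self.fixture is None:
            return raw
        base = self.base_raw_state_times()
        fixed = {
            self.intervention.name: self.fixture.state_times("intervention"),
            self.comparator.name: self.fixture.state_times("comparator"),
        }
        return {
            arm: tuple(
                max(0.0, fixed[arm][i] + raw[arm][i] - base[arm][i])
                for i in range(2)
            )
            for arm in raw
        }

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> CEResult:
        """Run the model, returning the incremental comparison."""
        overrides = dict(overrides or {})
        unknown = [
            k
            for k in overrides
            if k not in _COST_UTILITY_PARAMS
            and not any(
                k == f"{ep}_{arm}_{p}"
                for (arm, ep) in self.curves
                for p in ("shape", "rate", "intercept", "log_scale")
            )
        ]
        if unknown:
            raise KeyError(f"unrecognized parameters: {unknown}")

        drug = overrides.get("drug_cost_monthly", self.intervention.drug_cost_monthly)
        bsc = overrides.get("bsc_cost_monthly", self.intervention.bsc_cost_monthly)
        ae = overrides.get("ae_onetime_cost", self.intervention.ae_onetime_cost)
        ct = overrides.get("ct_cost_per_cycle", self.intervention.ct_cost_per_cycle)
        cross = overrides.get("crossover_fraction", self.comparator.crossover_fraction)
        config = replace(
            self.config,
            utility_pf=overrides.get("utility_pf", self.config.utility_pf),
            utility_pd=overrides.get("utility_pd", self.config.utility_pd),
        )
        arm_i = replace(
            self.intervention,
            drug_cost_monthly=drug,
            bsc_cost_monthly=bsc,
            ae_onetime_cost=ae,
            ct_cost_per_cycle=ct,
        )
        arm_c = replace(
            self.comparator,
            bsc_cost_monthly=bsc,
            ae_onetime_cost=ae,
            ct_cost_per_cycle=ct,
            crossover_fraction=cross,
        )

        times = self.state_times(overrides)
        st_i = times[arm_i.name]
        st_c = times[arm_c.name]
        cost_i = accrue_costs(st_i, arm_i, config, drug_reference=drug)
        cost_c = accrue_costs(st_c, arm_c, config, drug_reference=drug)
        qaly_i = accrue_qalys(st_i, config)
        qaly_c = accrue_qalys(st_c, config)
        res_i = ArmResult(arm_i.name, *cost_i, *qaly_i)
        res_c = ArmResult(arm_c.name, *cost_c, *qaly_c)

        incremental_qaly = None
        if self.fixture is not None:
            d_state = (sum(qaly_i) - sum(qaly_c))
            base_fixed_i = self.fixture.state_times("intervention")
            base_fixed_c = self.fixture.state_times("comparator")
            qaly_bi = accrue_qalys(base_fixed_i, self.config)
            qaly_bc = accrue_qalys(base_fixed_c, self.config)
            d_state_base = sum(qaly_bi) - sum(qaly_bc)
            if d_state_base != 0.0:
                incremental_qaly = (
                    self.fixture.incremental_qaly * d_state / d_state_base
                )
        return compare(res_i, res_c, incremental_qaly=incremental_qaly)

    def icer(self, overrides: Mapping[str, float] | None = None) -> float | None:
        return self.evaluate(overrides).icer


def default_model(calibrated: bool = True) -> CostEffectivenessModel:
    """The published base-case model; calibrated occupancy fixture by default."""
    from .economics import calibrate_fixture

    intervention, comparator = default_arms()
    fixture = calibrate_fixture() if calibrated else None
    return CostEffectivenessModel(
        intervention=intervention,
        comparator=comparator,
        curves=default_curves(),
        config=ModelConfig(),
        fixture=fixture,
    )
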