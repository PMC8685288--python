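"""Analysis configuration, result serialization and run logging.

An analysis is described by one YAML (or JSON) file validated against a
strict schema: two strategy-arm blocks, the cohort-model settings, one
survival-curve definition per arm and endpoint, and the sensitivity-analysis
settings.  Unknown keys are rejected with field-level messages.  The shipped
default configuration reproduces the published base case.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cohort import ModelConfig
from . import defaults as d
from .economics import ArmSpec, CEResult
from .model import CostEffectivenessModel
from .survival import SurvivalCurve, WeibullAFT, WeibullSR, make_hybrid_curve

logger = logging.getLogger("gistcea")

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_analysis_config",
    "build_model",
    "config_hash",
    "write_report",
    "read_report",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArmConfig(_Strict):
    name: str
    drug_cost_monthly: float = Field(ge=0)
    bsc_cost_monthly: float = Field(ge=0)
    ae_onetime_cost: float = Field(ge=0)
    ct_cost_per_cycle: float = Field(ge=0)
    crossover_fraction: float = Field(default=0.0, ge=0, le=1)
    include_ae: bool = True

    def to_spec(self) -> ArmSpec:
        return ArmSpec(**self.model_dump())


class CohortConfig(_Strict):
    cycle_len: float = Field(default=d.CYCLE_LEN_MONTHS, gt=0)
    horizon: float = Field(default=d.HORIZON_MONTHS, gt=0)
    annual_discount: float = Field(default=d.ANNUAL_DISCOUNT, ge=0, lt=1)
    half_cycle: bool = True
    utility_pf: float = Field(default=d.UTILITY_PF, ge=0, le=1)
    utility_pd: float = Field(default=d.UTILITY_PD, ge=0, le=1)
    structure: Literal["partitioned", "markov_competing"] = "partitioned"

    def to_model_config(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class CurveConfig(_Strict):
    type: Literal["weibull", "hybrid"] = "weibull"
    intercept: Optional[float] = None
    log_scale: Optional[float] = None
    gamma: Optional[float] = None
    lambda_: Optional[float] = Field(default=None, alias="lambda")
    km_file: Optional[str] = None
    junction: Optional[float] = None

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    @model_validator(mode="after")
    def _check(self) -> "CurveConfig":
        has_aft = self.intercept is not None and self.log_scale is not None
        has_sr = self.gamma is not None and self.lambda_ is not None
        if not (has_aft or has_sr):
            raise ValueError(
                "curve needs either (intercept, log_scale) or (gamma, lambda)"
            )
        if self.type == "hybrid" and (self.km_file is None or self.junction is None):
            raise ValueError("hybrid curve needs km_file and junction")
        return self

    def to_curve(self, base_dir: Path | None = None) -> SurvivalCurve:
        if self.gamma is not None and self.lambda_ is not None:
            tail = WeibullSR(shape=self.gamma, rate=self.lambda_)
        else:
            tail = WeibullAFT(
                intercept=self.intercept, log_scale=self.log_scale
            ).to_shape_rate()
        if self.type == "weibull":
            return tail
        km_path = Path(self.km_file)
        if base_dir is not None and not km_path.is_absolute():
            km_path = base_dir / km_path
        km = pd.read_csv(km_path)
        table = list(zip(km["time"].astype(float), km["survival"].astype(float)))
        if not table or table[0] != (0.0, 1.0):
            table = [(0.0, 1.0)] + [s for s in table if s[0] > 0.0]
        return make_hybrid_curve(table, tail, self.junction)


class SensitivityConfig(_Strict):
    one_way_fraction: float = Field(default=0.10, gt=0, lt=1)
    cost_cv: float = Field(default=0.2, ge=0)
    utility_cv: float = Field(default=0.1, ge=0)
    survival_se: float = Field(default=0.1, ge=0)
    psa_draws: int = Field(default=10_000, ge=1)
    price_grid: list[float] = Field(
        default_factory=lambda: [3200.0 * k for k in range(1, 11)]
    )
    wtp_start: float = Field(default=0.0, ge=0)
    wtp_stop: float = Field(default=300_000.0, gt=0)
    wtp_step: float = Field(default=5_000.0, gt=0)
    threshold_wtp: float = Field(default=d.WTP_REFERENCE, gt=0)

    def wtp_grid(self) -> list[float]:
        grid = []
        w = self.wtp_start
        while w <= self.wtp_stop + 1e-9:
            grid.append(round(w, 6))
            w += self.wtp_step
        return grid


class AnalysisConfig(_Strict):
    intervention: ArmConfig
    comparator: ArmConfig
    model: CohortConfig = Field(default_factory=CohortConfig)
    curves: dict[str, dict[Literal["os", "pfs"], CurveConfig]]
    use_fixture: bool = True
    sensitivity: SensitivityConfig = Field(default_factory=SensitivityConfig)
    seed: int = 20210
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check_curves(self) -> "AnalysisConfig":
        for arm in (self.intervention.name, self.comparator.name):
            if arm not in self.curves:
                raise ValueError(f"missing curve definitions for arm {arm!r}")
            for endpoint in ("os", "pfs"):
                if endpoint not in self.curves[arm]:
                    raise ValueError(f"missing {endpoint!r} curve for arm {arm!r}")
        return self


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate an analysis configuration from YAML/JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping, got {type(raw).__name__}")
    try:
        return AnalysisConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"{path}: invalid configuration:\n{exc}") from exc


def default_analysis_config() -> AnalysisConfig:
    """The shipped base-case configuration (published inputs verbatim)."""
    curves = {}
    for (arm, endpoint), aft in d.WEIBULL_AFT.items():
        curves.setdefault(arm, {})[endpoint] = CurveConfig(
            type="weibull", intercept=aft.intercept, log_scale=aft.log_scale
        )
    return AnalysisConfig(
        intervention=ArmConfig(
            name="ripretinib",
            drug_cost_monthly=d.DRUG_COST_MONTHLY,
            bsc_cost_monthly=d.BSC_COST_MONTHLY,
            ae_onetime_cost=d.AE_ONETIME_COST,
            ct_cost_per_cycle=d.CT_COST_PER_CYCLE,
            crossover_fraction=0.0,
        ),
        comparator=ArmConfig(
            name="placebo",
            drug_cost_monthly=0.0,
            bsc_cost_monthly=d.BSC_COST_MONTHLY,
            ae_onetime_cost=d.AE_ONETIME_COST,
            ct_cost_per_cycle=d.CT_COST_PER_CYCLE,
            crossover_fraction=d.CROSSOVER_FRACTION,
        ),
        curves=curves,
    )


def build_model(
    config: AnalysisConfig, base_dir: Path | None = None
) -> CostEffectivenessModel:
    """Instantiate the cost-effectiveness model described by a config."""
    from .economics import calibrate_fixture

    curves = {
        (arm, endpoint): cc.to_curve(base_dir)
        for arm, endpoints in config.curves.items()
        for endpoint, cc in endpoints.items()
    }
    intervention = config.intervention.to_spec()
    comparator = config.comparator.to_spec()
    model_config = config.model.to_model_config()
    fixture = None
    if config.use_fixture:
        fixture = calibrate_fixture(
            intervention=intervention, comparator=comparator, config=model_config
        )
    return CostEffectivenessModel(
        intervention=intervention,
        comparator=comparator,
        curves=curves,
        config=model_config,
        fixture=fixture,
    )


def config_hash(config: AnalysisConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(result: CEResult, path: str | Path) -> None:
    """Serialize a base-case result to JSON at full precision."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def read_report(path: str | Path) -> dict:
    """Parse a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
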