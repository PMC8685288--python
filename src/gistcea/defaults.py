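"""Published base-case inputs for the ripretinib-vs-placebo GIST analysis.

Every number here is a model *input*: the Weibull survival parameters fitted
to the INVICTUS fourth-line trial arms, 2021 US monthly costs, health-state
utilities, the placebo-arm crossover fraction, and the published base-case /
price-sensitivity result cells that the occupancy-fixture calibration targets
(see :mod:`gistcea.economics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .survival import WeibullAFT

# --- Weibull AFT survival parameters (time in months) ---------------------

WEIBULL_AFT: Mapping[tuple[str, str], WeibullAFT] = {
    ("ripretinib", "os"): WeibullAFT(intercept=2.782163, log_scale=-0.4285523),
    ("placebo", "os"): WeibullAFT(intercept=2.250612, log_scale=0.00098579),
    ("ripretinib", "pfs"): WeibullAFT(intercept=2.074947, log_scale=-0.09223515),
    ("placebo", "pfs"): WeibullAFT(intercept=0.830945, log_scale=-0.6655104),
}

# Published shape/rate values corresponding to the AFT rows above; used as a
# consistency check on the parameter mapping, not as an independent input.
WEIBULL_SHAPE_RATE: Mapping[tuple[str, str], tuple[float, float]] = {
    ("ripretinib", "os"): (1.535033646, 0.013971806),
    ("placebo", "os"): (0.999014696, 0.105568583),
    ("ripretinib", "pfs"): (1.096622663, 0.102752314),
    ("placebo", "pfs"): (1.945483243, 0.19857477),
}

# --- Costs (2021 USD), utilities, crossover -------------------------------

DRUG_COST_MONTHLY = 32_000.0       # ripretinib list price per 30 doses
BSC_COST_MONTHLY = 3_382.47        # best supportive care
AE_ONETIME_COST = 421.2            # grade 3-5 adverse-event management
CT_COST_PER_CYCLE = 1_365.39       # computed tomography surveillance
CROSSOVER_FRACTION = 29.0 / 44.0   # placebo patients crossing over at progression

UTILITY_PF = 0.767
UTILITY_PD = 0.647

ANNUAL_DISCOUNT = 0.03
CYCLE_LEN_MONTHS = 1.0
HORIZON_MONTHS = 240.0

WTP_REFERENCE = 150_000.0          # USD per QALY

# --- Published result cells used for fixture calibration ------------------


@dataclass(frozen=True)
class PublishedBaseCase:
    """Base-case result cells: per-state and total cost, per-state QALYs."""

    cost_pf_intervention: float = 234_808.0
    cost_pd_intervention: float = 25_297.0
    cost_pf_comparator: float = 9_505.0
    cost_pd_comparator: float = 180_349.0
    total_cost_intervention: float = 260_105.0
    total_cost_comparator: float = 189_854.0
    incremental_cost: float = 70_251.0
    icer: float = 244_010.0
    qaly_pf_intervention: float = 0.41
    qaly_pd_intervention: float = 0.40
    qaly_pf_comparator: float = 0.13
    qaly_pd_comparator: float = 0.39


@dataclass(frozen=True)
class PublishedPriceSweep:
    """Price sensitivity rows: price -> (intervention total cost, ΔC, ICER)."""

    rows: Mapping[float, tuple[float, float, float]] = field(
        default_factory=lambda: {
            3_200.0: (76_754.0, 26_807.0, 93_113.0),
            6_400.0: (97_127.0, 31_634.0, 109_879.0),
            9_600.0: (117_499.0, 36_461.0, 126_645.0),
            12_800.0: (137_871.0, 41_288.0, 143_412.0),
            16_000.0: (158_244.0, 46_115.0, 160_178.0),
            19_200.0: (178_616.0, 50_942.0, 176_944.0),
            22_400.0: (198_988.0, 55_769.0, 193_711.0),
            25_600.0: (219_361.0, 60_596.0, 210_477.0),
            28_800.0: (239_733.0, 65_424.0, 227_243.0),
            32_000.0: (260_105.0, 70_251.0, 244_010.0),
        }
    )


PUBLISHED_BASE_CASE = PublishedBaseCase()
PUBLISHED_PRICE_SWEEP = PublishedPriceSweep()
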