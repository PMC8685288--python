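"""Three-state cohort traces: progression-free, progressed, dead.

State occupancy can be built in two structural variants:

``partitioned``
    The partitioned-survival reading: PF occupancy is the PFS curve, death
    is one minus the OS curve, and progressed disease is the gap between
    them.  This is the standard construction when a model is parameterized
    directly by fitted OS and PFS curves.

``markov_competing``
    A state-transition variant in which the PFS and OS per-cycle hazards act
    as competing exit risks on the progression-free state, and progressed
    patients die at the OS hazard.  PF occupancy is therefore never larger
    than under the partitioned structure.

Person-time in a state is accumulated per cycle with an optional half-cycle
correction (averaging start- and end-of-cycle occupancy) and discounted with
an annual rate applied at the cycle midpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalCurve

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "CohortTrace", "build_trace", "state_time"]

_STRUCTURES = ("partitioned", "markov_competing")


@dataclass(frozen=True)
class ModelConfig:
    """Cycle structure, discounting and utility inputs of the cohort model.

    Cycle length defaults to one month so that per-cycle drug and care costs
    line up with the monthly prices; the lifetime horizon of 240 months is
    effectively unrestricted for these curves (survival < 0.1% well before).
    """

    cycle_len: float = 1.0
    horizon: float = 240.0
    annual_discount: float = 0.03
    half_cycle: bool = True
    utility_pf: float = 0.767
    utility_pd: float = 0.647
    structure: str = "partitioned"

    def __post_init__(self) -> None:
        if self.cycle_len <= 0:
            raise ValueError("cycle_len must be positive")
        n = self.horizon / self.cycle_len
        if self.horizon <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a positive multiple of cycle_len")
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError("annual_discount must lie in [0, 1)")
        for name in ("utility_pf", "utility_pd"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_len))

    def discount_factor(self, t_months) -> np.ndarray:
        return np.asarray(
            (1.0 + self.annual_discount) ** (-np.asarray(t_months, dtype=float) / 12.0)
        )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy of the three health states (index 0 = time 0)."""

    t: np.ndarray
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    structure: str = "partitioned"

    def __post_init__(self) -> None:
        total = self.pf + self.pd + self.dead
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("state occupancy must sum to 1 at every cycle")

    def to_frame(self, config: ModelConfig | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": np.arange(len(self.t)),
                "t_months": self.t,
                "pf": self.pf,
                "pd": self.pd,
                "dead": self.dead,
            }
        )
        if config is not None:
            df["discount_factor"] = config.discount_factor(self.t)
        return df


def build_trace(
    os_curve: SurvivalCurve, pfs_curve: SurvivalCurve, config: ModelConfig
) -> CohortTrace:
    """Build the per-cycle occupancy trace for one strategy arm."""
    t = np.arange(config.n_cycles + 1, dtype=float) * config.cycle_len
    s_os = np.asarray(os_curve.survival(t), dtype=float)
    s_pfs = np.asarray(pfs_curve.survival(t), dtype=float)

    if config.structure == "partitioned":
        if np.any(s_pfs > s_os + 1e-6):
            worst = float(np.max(s_pfs - s_os))
            logger.warning(
                "PFS exceeds OS at %d of %d cycles (max gap %.3g); "
                "clamping PD occupancy at 0",
                int(np.sum(s_pfs > s_os + 1e-6)), len(t), worst,
            )
        pf = np.minimum(s_pfs, s_os)
        dead = 1.0 - s_os
        pd_ = s_os - pf
        return CohortTrace(t=t, pf=pf, pd=pd_, dead=dead, structure=config.structure)

    # markov_competing: per-cycle conditional survival ratios give the
    # progression and death hazards acting on PF as competing risks.
    n = config.n_cycles
    pf = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    pf[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    for k in range(1, n + 1):
        r_os = s_os[k] / s_os[k - 1] if s_os[k - 1] > 0 else 0.0
        r_pfs = s_pfs[k] / s_pfs[k - 1] if s_pfs[k - 1] > 0 else 0.0
        r_os = min(max(r_os, 0.0), 1.0)
        r_pfs = min(max(r_pfs, 0.0), 1.0)
        stay = r_pfs * r_os
        exit_prob = 1.0 - stay
        if exit_prob > 0 and r_pfs > 0 and r_os > 0:
            h_prog = -math.log(r_pfs)
            h_death = -math.log(r_os)
            w_death = h_death / (h_prog + h_death) if h_prog + h_death > 0 else 0.0
        else:
            # one of the ratios hit zero: attribute the exit to that cause
            w_death = 1.0 if r_os == 0.0 else 0.0
        q_pd_death = 1.0 - r_os
        pf[k] = pf[k - 1] * stay
        pd_[k] = pd_[k - 1] * (1.0 - q_pd_death) + pf[k - 1] * exit_prob * (1.0 - w_death)
        dead[k] = dead[k - 1] + pd_[k - 1] * q_pd_death + pf[k - 1] * exit_prob * w_death
    return CohortTrace(t=t, pf=pf, pd=pd_, dead=dead, structure=config.structure)


def state_time(
    trace: CohortTrace,
    state: str,
    config: ModelConfig,
    discounted: bool = True,
) -> float:
    """Person-time (months) spent in ``state`` over the trace.

    With the half-cycle correction the occupancy credited to cycle k is the
    average of the start- and end-of-cycle values (the trapezoid rule);
    otherwise it is the end-of-cycle value.  Discounting applies the annual
    rate at each cycle midpoint.
    """
    occ = {"pf": trace.pf, "pd": trace.pd, "dead": trace.dead}[state]
    delta = config.cycle_len
    if config.half_cycle:
        per_cycle = 0.5 * (occ[:-1] + occ[1:])
    else:
        per_cycle = occ[1:]
    if discounted:
        midpoints = (np.arange(1, len(occ)) - 0.5) * delta
        per_cycle = per_cycle * config.discount_factor(midpoints)
    return float(np.sum(per_cycle) * delta)
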