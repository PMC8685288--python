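"""Pseudo individual-patient time-to-event data and Kaplan–Meier estimation.

The published survival inputs are Weibull fits to digitized trial curves;
the underlying patient-level data are not available.  This module generates
right-censored pseudo individual patient data (IPD) with the structure the
fitting stage assumes — per-arm Weibull event times with administrative
(type I) censoring and an optional uniform accrual window — so the censored
maximum-likelihood fitting and hybrid-curve machinery can be exercised
end to end.  Arm sizes default to the fourth-line trial's placebo arm
(n = 44) and a configurable intervention arm (n = 85).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import IPDRecord, WeibullSR

__all__ = [
    "SimSpec",
    "KMCurve",
    "simulate_ipd",
    "km_estimate",
    "ipd_to_frame",
    "ipd_from_frame",
]

DEFAULT_N_COMPARATOR = 44
DEFAULT_N_INTERVENTION = 85


@dataclass(frozen=True)
class SimSpec:
    """Specification for one simulated arm/endpoint."""

    n: int
    curve: WeibullSR
    admin_censor_time: float
    seed: int
    arm: str = ""
    accrual_window: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.admin_censor_time < 0:
            raise ValueError("admin_censor_time must be nonnegative")
        if self.accrual_window < 0:
            raise ValueError("accrual_window must be nonnegative")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step times, survival values, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, len(self.survival) - 1)], 1.0)

    def as_table(self) -> list[tuple[float, float]]:
        """(time, survival) steps starting at (0, 1), for hybrid curves."""
        steps = [(0.0, 1.0)]
        for t, s in zip(self.times, self.survival):
            if t > 0.0:
                steps.append((float(t), float(s)))
        return steps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_risk": self.n_risk}
        )


def simulate_ipd(spec: SimSpec) -> list[IPDRecord]:
    """Draw right-censored Weibull event times by inverse-CDF sampling.

    Event times are t = (-ln U / rate)**(1/shape); each subject is censored
    administratively at ``admin_censor_time`` minus their accrual offset
    (uniform over ``accrual_window`` when enabled).  Reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    times = (-np.log(u) / spec.curve.rate) ** (1.0 / spec.curve.shape)
    if spec.accrual_window > 0:
        entry = rng.uniform(0.0, spec.accrual_window, size=spec.n)
        censor = np.maximum(spec.admin_censor_time - entry, 0.0)
    else:
        censor = np.full(spec.n, spec.admin_censor_time)
    observed = times <= censor
    out_times = np.where(observed, times, censor)
    return [
        IPDRecord(time=float(t), event=bool(e), arm=spec.arm)
        for t, e in zip(out_times, observed)
    ]


def km_estimate(data: list[IPDRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator of the survivor function."""
    if len(data) == 0:
        raise ValueError("no data")
    t = np.asarray([r.time for r in data], dtype=float)
    e = np.asarray([r.event for r in data], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    # at-risk counts just before each step time
    order = np.sort(t)
    n_risk = len(t) - np.searchsorted(order, times, side="left")
    return KMCurve(times=times, survival=survival, n_risk=n_risk.astype(int))


def ipd_to_frame(data: list[IPDRecord]) -> pd.DataFrame:
    """IPD as a data frame with columns time_months, event, arm."""
    return pd.DataFrame(
        {
            "time_months": [r.time for r in data],
            "event": [int(r.event) for r in data],
            "arm": [r.arm for r in data],
        }
    )


def ipd_from_frame(df: pd.DataFrame) -> list[IPDRecord]:
    """Inverse of :func:`ipd_to_frame`."""
    required = {"time_months", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"IPD frame must have columns {sorted(required)}")
    arms = df["arm"] if "arm" in df.columns else [""] * len(df)
    return [
        IPDRecord(time=float(t), event=bool(int(e)), arm=str(a))
        for t, e, a in zip(df["time_months"], df["event"], arms)
    ]
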