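"""Weibull survival curves for cohort-model extrapolation.

Time-to-event endpoints (overall survival, progression-free survival) are
modelled with two-parameter Weibull distributions, expressed either in the
accelerated-failure-time (AFT) parameterization used by most fitting software
(``intercept`` = location on the log-time scale, ``log_scale`` = log of the
AFT dispersion) or in the shape/rate parameterization used for direct curve
evaluation,

    S(t) = exp(-lambda * t**gamma),      gamma = exp(-log_scale),
                                         lambda = exp(-gamma * intercept).

Time is measured in months throughout.  The module also supports hybrid
curves — a Kaplan–Meier step function over the observed follow-up with a
proportional Weibull tail beyond a junction time — and censored maximum
likelihood fitting of the AFT parameters from individual patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import optimize

__all__ = [
    "SurvivalCurve",
    "WeibullAFT",
    "WeibullSR",
    "HybridCurve",
    "IPDRecord",
    "WeibullAFTFit",
    "aft_to_shape_rate",
    "survival_at",
    "median_survival",
    "restricted_mean",
    "per_cycle_exit_prob",
    "make_hybrid_curve",
    "fit_weibull_aft",
]


@runtime_checkable
class SurvivalCurve(Protocol):
    """Anything exposing a vectorized survivor function ``survival(t)``."""

    def survival(self, t):  # pragma: no cover - protocol stub
        ...


@dataclass(frozen=True)
class WeibullAFT:
    """Weibull in accelerated-failure-time form (log-months location)."""

    intercept: float
    log_scale: float

    def to_shape_rate(self) -> "WeibullSR":
        return aft_to_shape_rate(self)

    def survival(self, t):
        return self.to_shape_rate().survival(t)


@dataclass(frozen=True)
class WeibullSR:
    """Weibull in shape/rate form: S(t) = exp(-rate * t**shape)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError(f"rate must be positive and finite, got {self.rate}")

    def survival(self, t):
        t = _check_times(t)
        return np.exp(-self.rate * np.power(t, self.shape))

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.rate * self.shape * np.power(t, self.shape - 1.0)

    def median(self) -> float:
        return float((math.log(2.0) / self.rate) ** (1.0 / self.shape))

    def mean(self) -> float:
        """E[T] = rate**(-1/shape) * Gamma(1 + 1/shape)."""
        return float(self.rate ** (-1.0 / self.shape) * math.gamma(1.0 + 1.0 / self.shape))

    def to_aft(self) -> WeibullAFT:
        log_scale = -math.log(self.shape)
        intercept = -math.log(self.rate) / self.shape
        return WeibullAFT(intercept=intercept, log_scale=log_scale)


@dataclass(frozen=True)
class HybridCurve:
    """Kaplan–Meier step function with a proportional Weibull tail.

    For t <= junction the curve follows the step function; beyond the
    junction the Weibull tail is grafted on proportionally,
    ``S(t) = S_km(junction) * S_tail(t) / S_tail(junction)``, so the curve
    is continuous at the junction and inherits the tail's conditional
    survival thereafter.
    """

    km_times: tuple = field(default=())
    km_survival: tuple = field(default=())
    tail: WeibullSR = field(default=None)  # type: ignore[assignment]
    junction: float = 0.0

    def _km_at(self, t):
        t = np.asarray(t, dtype=float)
        if len(self.km_times) == 0:
            return np.ones_like(t)
        times = np.asarray(self.km_times)
        surv = np.asarray(self.km_survival)
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out

    def survival(self, t):
        t = _check_times(t)
        s_junction = float(self._km_at(self.junction))
        tail_ref = float(self.tail.survival(self.junction))
        before = self._km_at(t)
        after = s_junction * self.tail.survival(t) / tail_ref
        return np.where(t <= self.junction, before, after)


@dataclass(frozen=True)
class IPDRecord:
    """One (pseudo) individual-patient observation: a time and event flag."""

    time: float
    event: bool
    arm: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"time must be finite and nonnegative, got {self.time}")


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be nonnegative")
    return t


def aft_to_shape_rate(p: WeibullAFT) -> WeibullSR:
    """Convert (intercept, log_scale) to (shape, rate).

    shape = exp(-log_scale); rate = exp(-shape * intercept).
    """
    shape = math.exp(-p.log_scale)
    rate = math.exp(-shape * p.intercept)
    return WeibullSR(shape=shape, rate=rate)


def survival_at(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Evaluate S(t); scalar in, scalar out."""
    t_arr = _check_times(t)
    s = np.asarray(curve.survival(t_arr), dtype=float)
    if s.ndim == 0 or np.isscalar(t):
        return float(s)
    return s


def median_survival(curve: SurvivalCurve, horizon: float = 1200.0) -> float:
    """Time at which S(t) = 0.5.

    Closed form for Weibull curves; bisection (to 1e-8 months) otherwise.
    Raises ``ValueError`` if the curve never crosses 0.5 within ``horizon``.
    """
    if isinstance(curve, WeibullAFT):
        curve = curve.to_shape_rate()
    if isinstance(curve, WeibullSR):
        m = curve.median()
        if m > horizon:
            raise ValueError("median exceeds search horizon")
        return m
    if float(survival_at(curve, horizon)) > 0.5:
        raise ValueError("curve does not reach 0.5 within the search horizon")
    lo, hi = 0.0, float(horizon)
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if float(survival_at(curve, mid)) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def restricted_mean(
    curve: SurvivalCurve,
    horizon: float,
    annual_discount: float = 0.0,
    grid_step: float = 0.1,
) -> float:
    """Discounted restricted mean survival time over [0, horizon] in months.

    Computes the integral of S(t) * (1 + annual_discount)**(-t/12) by the
    composite trapezoid rule on a fine (default 0.1-month) grid; with a zero
    discount rate this is the ordinary RMST.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if annual_discount < 0:
        raise ValueError("annual_discount must be nonnegative")
    n = max(int(round(horizon / grid_step)), 1)
    t = np.linspace(0.0, horizon, n + 1)
    s = np.asarray(curve.survival(t), dtype=float)
    disc = (1.0 + annual_discount) ** (-t / 12.0)
    return float(np.trapezoid(s * disc, t))


def per_cycle_exit_prob(curve: SurvivalCurve, cycle_index: int, cycle_len: float) -> float:
    """Probability of leaving the curve's state during cycle ``cycle_index``.

    p_k = 1 - S(k * delta) / S((k-1) * delta), conditional on being in the
    state at the start of the cycle.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    prev = float(survival_at(curve, (cycle_index - 1) * cycle_len))
    if prev <= 0.0:
        raise ValueError("cohort exhausted: survival is zero at the cycle start")
    cur = float(survival_at(curve, cycle_index * cycle_len))
    p = 1.0 - cur / prev
    return min(max(p, 0.0), 1.0)


def make_hybrid_curve(
    km_table: Sequence[tuple[float, float]],
    tail: WeibullSR,
    junction: float,
) -> HybridCurve:
    """Graft a Weibull tail onto a Kaplan–Meier step function at ``junction``.

    ``km_table`` is a sequence of (time, survival) steps starting at (0, 1)
    with nonincreasing survival.  An empty table with junction 0 yields the
    pure Weibull tail.
    """
    if junction < 0:
        raise ValueError("junction must be nonnegative")
    if len(km_table) == 0:
        if junction > 0:
            raise ValueError("junction lies beyond the (empty) KM table")
        return HybridCurve(km_times=(), km_survival=(), tail=tail, junction=0.0)
    times = [float(t) for t, _ in km_table]
    surv = [float(s) for _, s in km_table]
    if times[0] != 0.0 or surv[0] != 1.0:
        raise ValueError("km_table must start at (0, 1)")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("km_table times must be strictly increasing")
    if any(s2 > s1 for s1, s2 in zip(surv, surv[1:])):
        raise ValueError("km_table survival must be nonincreasing")
    if junction > times[-1]:
        raise ValueError("junction lies beyond the KM table range")
    return HybridCurve(
        km_times=tuple(times), km_survival=tuple(surv), tail=tail, junction=float(junction)
    )


@dataclass(frozen=True)
class WeibullAFTFit:
    """Censored Weibull MLE on the AFT scale with observed-information SEs."""

    intercept: float
    log_scale: float
    se_intercept: float
    se_log_scale: float
    cov: np.ndarray
    log_likelihood: float
    n_events: int
    n_censored: int

    @property
    def params(self) -> WeibullAFT:
        return WeibullAFT(intercept=self.intercept, log_scale=self.log_scale)

    def to_shape_rate(self) -> WeibullSR:
        return self.params.to_shape_rate()


def _weibull_negloglik(theta, t, event):
    mu, s = theta
    shape = math.exp(-s)
    log_rate = -shape * mu
    log_t = np.log(t)
    cum_haz = np.exp(log_rate + shape * log_t)
    ll = np.sum(event * (log_rate + math.log(shape) + (shape - 1.0) * log_t)) - np.sum(cum_haz)
    return -ll


def _numeric_hessian(fun, x, args=(), eps=1e-5):
    x = np.asarray(x, dtype=float)
    k = len(x)
    hess = np.empty((k, k))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(x + ei + ej, *args)
            fpm = fun(x + ei - ej, *args)
            fmp = fun(x - ei + ej, *args)
            fmm = fun(x - ei - ej, *args)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def fit_weibull_aft(data: Sequence[IPDRecord]) -> WeibullAFTFit:
    """Fit a right-censored Weibull by maximum likelihood on the AFT scale.

    The unconstrained (intercept, log_scale) parameterization needs no
    positivity constraints; standard errors come from the inverse of the
    numerically differenced Hessian of the negative log-likelihood.
    Requires at least two observed events and strictly positive times.
    """
    t = np.asarray([r.time for r in data], dtype=float)
    event = np.asarray([r.event for r in data], dtype=float)
    if len(t) == 0:
        raise ValueError("no data")
    if np.any(t <= 0):
        raise ValueError("all times must be strictly positive for fitting")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 observed events to fit, got {n_events}")

    log_te = np.log(t[event > 0])
    mu0 = float(np.mean(log_te))
    sd0 = float(np.std(log_te))
    s0 = math.log(max(sd0, 1e-2))
    res = optimize.minimize(
        _weibull_negloglik,
        x0=np.array([mu0, s0]),
        args=(t, event),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    res = optimize.minimize(
        _weibull_negloglik, x0=res.x, args=(t, event), method="BFGS",
        options={"gtol": 1e-8},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("Weibull fit did not converge")
    hess = _numeric_hessian(_weibull_negloglik, res.x, args=(t, event))
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
        raise RuntimeError("observed information matrix is singular") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return WeibullAFTFit(
        intercept=float(res.x[0]),
        log_scale=float(res.x[1]),
        se_intercept=float(se[0]),
        se_log_scale=float(se[1]),
        cov=cov,
        log_likelihood=float(-res.fun),
        n_events=n_events,
        n_censored=int(len(t) - n_events),
    )
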