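# Methods

## Survival model

Each arm/endpoint is a two-parameter Weibull, S(t) = exp(−λ t^γ), t in
months. The published fits are given on the accelerated-failure-time (AFT)
scale (intercept μ, log-scale s); the mapping γ = e^(−s), λ = e^(−γμ)
reproduces the published (γ, λ) rows to better than 0.1% relative, and the
implied placebo overall-survival median (6.58 months) rounds to the trial's
6.6 months — which also fixes the time unit as months. Hybrid curves (a
Kaplan–Meier step function with a proportional Weibull tail grafted at a
junction time) are supported for workflows where the observed portion of the
curve is available; the published analysis's own KM steps are not
recoverable, which drives the calibration described below.

Censored Weibull fitting maximizes the right-censored log-likelihood on the
unconstrained (μ, s) scale (Nelder–Mead polish then BFGS); standard errors
come from the inverse of a central-difference Hessian. The exponential
special case (γ = 1, rate MLE = events / person-time) and lifelines'
`WeibullFitter` serve as independent cross-checks in the test suite.

## Cohort model

Three mutually exclusive states: progression-free (PF), progressed disease
(PD), dead. Default structure is **partitioned survival**: PF = S_PFS,
dead = 1 − S_OS, PD = the gap. Partitioned occupancy is the standard reading
of a model parameterized directly by fitted OS/PFS curves and is what
reproduces the published placebo-arm effectiveness (0.13 / 0.39 / 0.52
QALYs) from the raw curves. Because independent fits can transiently put
S_PFS above S_OS, PD is clamped at zero (with a warning above numerical
noise) and PF capped at S_OS so occupancy always sums to one. A
**competing-hazard Markov** variant is provided as a structural alternative:
the per-cycle PFS and OS conditional-survival ratios act as competing exit
hazards on PF (exits split in proportion to the cumulative hazards), and PD
patients die at the OS hazard; its PF occupancy is provably no larger than
the partitioned one.

Cycles are 1 month (the trial's 28-day schedule is a dosing calendar, not a
model constraint; monthly cycles match the monthly prices). Horizon is 240
months — a lifetime for these curves (cohort survival < 0.1% well before).
Person-time uses the half-cycle correction (start/end occupancy averaging,
i.e. the trapezoid rule) and a 3%-per-annum discount factor evaluated at
each cycle midpoint. Halving the cycle length moves state person-time by
< 1%, so the monthly grid is within rounding precision of the continuous
limit. Restricted means are integrated by composite trapezoid on a 0.1-month
grid (error ≪ reporting precision); Weibull medians are closed-form,
hybrid-curve medians bisected to 1e-8 months.

## Costs, QALYs and the occupancy fixture

Monthly inputs (2021 USD): drug $32,000 (intervention PF only), best
supportive care $3,382.47 (both states, both arms), CT $1,365.39 (PF only),
adverse-event management $421.2 once at entry (both arms — the $421
difference is below the dollar-rounding resolution either way, so this is
configurable), utilities 0.767 (PF) / 0.647 (PD). In the comparator arm the
crossover fraction 29/44 accrues the full intervention drug price for its
entire PD occupancy. This recipe was chosen because it reproduces all four
published per-state cost cells from the state times to within rounding
noise; the published tables do not state the accrual rules explicitly.

The published intervention-arm PF occupancy (≈ 6.4 discounted months) lies
between the partitioned (≈ 7.6) and competing-hazard (≈ 5.8) values computed
from the pure Weibulls — consistent with a KM-plus-tail hybrid base trace
whose steps are not recoverable. Rather than guess the steps, the base case
carries a **state-time fixture**: the four discounted state times are
inverted exactly from the four published cost cells, the unrounded
incremental QALYs are set to (incremental cost)/(ICER) = 70,251/244,010 ≈
0.28790, and all five are refined by weighted least squares against every
published base-case and price-sensitivity cell, each weighted by its printed
rounding precision ($1 for dollar cells, 0.005 for QALY cells). The refit is
needed because the published tables are not perfectly self-consistent: the
cost cells imply a drug-price sensitivity (discounted drug-month
differential D = PF_ripretinib − (29/44)·PD_placebo) of 1.521 months/$,
while the price table is exactly affine with D = 1.508. The compromise keeps
arm totals, incremental cost and the ICER exact to the printed dollar,
every price-table cell within 0.15%, and the headline per-state cells
(PF cost $234,808; placebo PD cost $180,349) within 0.15%, at the price of
~1–2% drift in the two small per-state cost cells and the intervention
per-state QALY split. The fixture's incremental QALYs are therefore carried
as their own calibrated quantity, not forced to equal the difference of the
arm QALY totals (they agree after rounding: 0.29).

With a fixture active, survival-parameter perturbations propagate as
**deltas**: each arm/state time is the fixture value plus the change the
perturbation induces in the raw partitioned trace (clamped at zero), and
incremental QALYs scale by the relative change in the state-time/utility
QALY difference — so the unperturbed model reproduces the published base
case exactly, utility rescaling propagates multiplicatively, and price
changes stay exactly affine. Without a fixture everything comes straight
from the traces.

## Sensitivity analysis

**One-way (tornado).** Bounds default to ±10% of base, acting
multiplicatively on (γ, λ): the paper's single disclosed perturbed value
(placebo OS γ → 0.89911 = 0.9 × 0.999015) pins this convention. ICERs at
each bound are tabulated and ordered by range width; dominant/dominated
bounds are flagged and excluded from the ordering. Under the calibrated
model, lowering the placebo OS shape lengthens placebo survival enough that
the crossover drug bill makes ripretinib outright dominant — the extreme of
the published "ICER drops" direction (the milder published extreme,
$127,399, depends on the unrecoverable hybrid base trace and is treated as
directional only).

**Price machinery.** Incremental cost is affine in the monthly price with
slope D, so the threshold price solves linearly; a bisection fallback (to
$0.50) covers non-linear recipes. The $150,000/QALY threshold lands at
$14,061/month against the published $14,057 — a 56% discount either way.

**Probabilistic.** Costs are gamma-distributed and utilities
beta-distributed, moment-matched to (base, CV); Weibull parameters are
normal on the unconstrained (μ, s) scale so derived (γ, λ) stay positive.
The published analysis does not state its dispersions; defaults are CV 0.2
for costs, CV 0.1 for utilities, SE 0.1 for μ and s — all configurable. Each
parameter draws from an independent RNG stream keyed by (root seed,
parameter name), so adding a parameter never reshuffles the others. The
acceptability curve (CEAC) reports the fraction of draws with nonnegative
net monetary benefit w·ΔE − ΔC. With the defaults and 10,000 draws the
probability ripretinib is cost-effective at $150k/QALY is ≈ 0.20 — below
the published 41.1%, as expected given the unstated published variances and
the full-Weibull (rather than tail-only) propagation of survival
uncertainty; the qualitative conclusion (well under 50%) is robust, and the
CEAC checks are treated as band/shape checks, not point targets.

## Synthetic data

`gistcea.synthetic` generates pseudo individual-patient data by inverse-CDF
Weibull sampling with administrative (type I) censoring and an optional
uniform accrual window, defaulting to the trial's placebo arm size (n = 44;
intervention default 85, configurable — the trial's intervention arm size is
not an input to the model). This emulates the structure the fitting stage
assumes — independent censoring at a fixed analysis date — but not
real-trial features such as dropout, interval-censored progression
assessment, or the crossover-induced dependence between arms; passing
round-trip tests therefore validates the estimators under the stated
sampling model, not against trial idiosyncrasies. The Kaplan–Meier
estimator (via lifelines) supports fit diagnostics and hybrid-curve
construction, and is tested against a hand product-limit calculation.

## Problem sizes and numerical choices

Default runs use 240 monthly cycles; parameter-recovery tests use n =
2,000–5,000 subjects over 10–20 seeds; the PSA uses 10,000 draws (a few
seconds). Degenerate inputs are defined errors: all-censored data is
unfittable; a curve that never crosses 0.5 has no median; an exhausted
cohort has no conditional exit probability; a WTP below the zero-price ICER
has no threshold price; zero incremental QALYs yields an "undefined" flag
rather than a division.

## Known limitations

- The trial's KM step functions, per-event adverse-event frequencies and
  PSA variances are unpublished; the fixture and default dispersions carry
  those gaps explicitly rather than silently.
- Crossover drug exposure is modelled for the full PD occupancy (this is
  what matches the published PD cost cell); a shorter on-treatment window
  would lower the placebo arm's cost.
- No treatment-sequence scenarios, EVPI, time-varying utilities, tunnel
  states, or cost inflation adjustments.
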