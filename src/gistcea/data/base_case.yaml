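# Shipped base-case configuration: published inputs for fourth-line
# ripretinib versus placebo in advanced GIST (2021 USD, time in months).
intervention:
  name: ripretinib
  drug_cost_monthly: 32000.0
  bsc_cost_monthly: 3382.47
  ae_onetime_cost: 421.2
  ct_cost_per_cycle: 1365.39
  crossover_fraction: 0.0
comparator:
  name: placebo
  drug_cost_monthly: 0.0
  bsc_cost_monthly: 3382.47
  ae_onetime_cost: 421.2
  ct_cost_per_cycle: 1365.39
  crossover_fraction: 0.6590909090909091
model:
  cycle_len: 1.0
  horizon: 240.0
  annual_discount: 0.03
  half_cycle: true
  utility_pf: 0.767
  utility_pd: 0.647
  structure: partitioned
curves:
  ripretinib:
    os: {type: weibull, intercept: 2.782163, log_scale: -0.4285523}
    pfs: {type: weibull, intercept: 2.074947, log_scale: -0.09223515}
  placebo:
    os: {type: weibull, intercept: 2.250612, log_scale: 0.00098579}
    pfs: {type: weibull, intercept: 0.830945, log_scale: -0.6655104}
use_fixture: true
sensitivity:
  one_way_fraction: 0.10
  cost_cv: 0.2
  utility_cv: 0.1
  survival_se: 0.1
  psa_draws: 10000
  price_grid: [3200.0, 6400.0, 9600.0, 12800.0, 16000.0, 19200.0, 22400.0, 25600.0, 28800.0, 32000.0]
  wtp_start: 0.0
  wtp_stop: 300000.0
  wtp_step: 5000.0
  threshold_wtp: 150000.0
seed: 20210
output_dir: results
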