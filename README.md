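# carecast

Open-cohort multi-state Markov projection of cardiovascular disease (CVD),
cognitive impairment (CI), functional impairment (FI) and dementia for an
ageing population, with health-economic scenario comparison: health and
social care costs, the opportunity cost of informal care, and quality-
adjusted life years (QALYs), under counterfactual CVD-incidence scenarios.

It is written for health economists and epidemiological modellers who want a
tested, reproducible pipeline for questions of the form *"what does a
persistent plateau in CVD incidence cost, relative to a continued decline?"*

## The model

The population aged 35–100 is tracked by single year of age, sex and health
state. Eight living states are defined by three morbidity flags — CVD, CI
and FI — with dementia defined as concurrent CI and FI:

```
FREE, CVD, CI, FI, CVD+CI, CVD+FI, DEM (=CI+FI), CVD+DEM
```

plus two absorbing states, CVD death and non-CVD death. Each year every
cohort moves according to transition probabilities
`p(to | from, age, sex, year)`; survivors age one year; a new disease-free
cohort enters at 35; deaths accumulate.

The components, each estimable from data:

- **Transitions** — two-year incidence of CVD, CI, FI and recovery from FI
  by logistic regression on a biennial panel (age, sex, current-state
  indicators), annualized by `p₁ = 1 − (1 − p₂)^(1/2)`, with calendar
  effects: CI incidence declines 2.7 %/yr, and CVD incidence follows the
  scenario — **PLATEAU** holds age-specific CVD incidence at its 2011
  level, **FALL** continues the fitted 1991–2011 log-linear decline.
- **Mortality** — a three-step model: (1) population cause-specific death
  rates projected by a log-linear age–period fit to historical rates in
  5-year bands; (2) state contrasts (death odds by health state) from panel
  data; (3) an additive logit offset solved per cell so the
  state-occupancy-weighted mean reproduces the population rate exactly.
- **Costs** — hospital (OLS on the record-linked consenting subsample,
  imputed to non-consenters), prescribing (formulary unit costs + two-part
  model), formal social care (two-part probit + OLS on weekly hours;
  probit × flat annual cost for daycare and residential care) and informal
  care (two-part hours valued at £7.76/h); healthcare calibrated to external
  totals by age band; everything expressed in 2019 prices.
- **Utilities** — EQ-5D per cell: population norm × disease multipliers
  (dementia superseding CI) with −0.042 per ADL limitation, clamped to
  [−0.594, 1].
- **Economics** — cumulative 2020–2029 costs and QALYs per scenario;
  net monetary cost = Δcosts + λ·(QALYs lost), λ = £60,000 (sensitivity
  £30,000); excess (attributable) disease costs via a counterfactual state
  remap; probabilistic sensitivity analysis with ±20 % beta cost
  multipliers and multivariate-normal coefficient draws.

A synthetic-data module generates a biennial ageing panel and demographic
series from a fully known ground truth, so every estimation stage is tested
by parameter recovery without any external download.

## Worked example

```python
from carecast import CareTrajectoryModel

model = CareTrajectoryModel.from_synthetic(seed=1, n_individuals=20_000)
results = model.fit()          # fits transitions, mortality, costs, utilities
print(results.summary())
```

```
Care-trajectory scenario comparison (PLATEAU - FALL)
========================================================
Outcome window          2020-2029  (GBP 2019 prices)
QALY value              GBP 60,000
Discounting             costs 0.0%, QALYs 0.0%
Fitted CVD trend (FALL) -4.000%/yr
--------------------------------------------------------
D healthcare costs      GBP      12.05 bn
D social care costs     GBP       4.94 bn
D informal care value   GBP       1.99 bn
D total costs           GBP      18.98 bn
D QALYs                       -781,801
Value of QALYs lost     GBP      46.91 bn
Net monetary cost       GBP      65.89 bn
--------------------------------------------------------
CVD incidence 2029: PLATEAU 849 vs FALL 437 per 100,000
CVD prevalence 2029: PLATEAU 9.6% vs FALL 6.6%
```

Reading: if CVD incidence stays flat instead of continuing to fall, the
synthetic England-and-Wales-scale population pays an extra £19.0bn in care
costs over 2020–2029 and loses 782 thousand QALYs, a net monetary cost of
£65.9bn at £60,000 per QALY. The deltas are positive for every cost
category because higher CVD incidence raises CVD prevalence (9.6 % vs 6.6 %
of 35–100-year-olds by 2029) and, downstream, disability and dementia.

Other entry points on the results object: `results.project(scenario)`,
`results.economics(scenario, EconConfig(...))`, `results.excess_costs("CVD",
2020)`, `results.cost_of_illness("DEMENTIA", 2020)`,
`results.run_psa(PSAConfig(n_draws=1000, seed=0))`,
`results.plot_epidemiology()`. A `carecast` CLI wraps the same pipeline
(`simulate`, `estimate`, `project`, `compare`, `psa`, `validate`).

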