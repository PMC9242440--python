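# Methods

This note documents the model, the estimation stages, the synthetic data
generator, numerical choices, and known limitations. It describes what the
code computes; every number quoted is produced by the test suite or
`scripts/acceptance.py` at run time.

## State space and transition structure

Living states are the eight combinations of three morbidity flags — CVD,
cognitive impairment (CI), functional impairment (FI) — that arise when
dementia is defined as CI ∧ FI, plus two absorbing cause-of-death states
(CVD death, non-CVD death). Four incident transitions are modelled: CVD
onset, CI onset, FI onset, FI recovery. The permitted-transition graph is
the simplest one consistent with those events: CVD and CI are irreversible;
FI is recoverable until dementia is reached (dementia is irreversible); at
most one flag changes per annual cycle, so dementia is entered by acquiring
the missing impairment on top of an existing one. New 35-year-old entrants
are all disease-free — at that age true prevalence of any flag is small
enough that the misclassification is negligible.

## Transition probabilities

Two-year incidence logits are fitted per transition kind on wave-to-wave
panel observations with intercept, centred age (age − 70), sex, and
current-state indicators; state indicators enter only where the risk set
varies on them. Observations that die before the next wave are excluded:
incidence is estimated conditional on survival, which matches how the
annual table composes survival with conditional movement. Zero-variance
covariates in a risk set are dropped rather than producing a singular fit,
so degenerate designs (single covariate pattern) collapse to the
intercept-only MLE.

**Annualization.** One-year probabilities are
`p₁ = 1 − (1 − p₂)^(1/2)` per off-diagonal entry, with the stay
probability filling the row. This is exact under independent competing
risks with a constant hazard within the interval; the matrix-root
alternative can produce negative entries and is not used. If annualized
off-diagonal mass exceeds one (possible only at extreme inputs), the row is
renormalized and a warning logged.

**Calendar effects.** CI onset is scaled by (1 − 0.027)^(year − 2011),
a secular decline in cognitive-impairment incidence. CVD onset follows the
scenario: both scenarios share the historical trend up to 2011; after 2011
PLATEAU freezes the factor at its 2011 value while FALL continues
(1 + trend)^(year − 2011). The trend is not a constant in the code: it is
fitted by log-linear regression of historical CVD mortality rates on year
over 1991–2011 (incidence mirroring mortality trends), which recovers
−4 %/yr from the packaged synthetic series. Scaled probabilities are
clamped to [0, 1].

## Mortality (three steps)

1. **Population projection.** Per (cause, 5-year age band, sex), log rate
   is regressed on calendar year and extrapolated to the horizon (a
   deterministic log-linear age–period model; a Bayesian age-period-cohort
   stack would be out of proportion for a desk-scale package and is out of
   scope). Band projections are interpolated to single year of age
   piecewise-linearly on the log scale at band midpoints with constant
   extrapolation beyond the outer midpoints. At least 10 historical years
   per series are required.
2. **State contrasts.** Two death logits per cause on panel data: a
   reference model (sex, age group 50–59/60–69/70–79/80+, interactions)
   and a full model adding the three state flags. State odds multipliers
   are exp of the flag coefficients. Ages 90+ are pooled with 80–89.
3. **Calibration.** For every (cause, age, sex, year) cell an additive
   logit offset k solves
   `Σ_s occ_s · expit(logit(q_pop) + k + log OR_s) = q_pop`,
   so state contrasts are preserved exactly while the occupancy-weighted
   mixture reproduces the population rate exactly (population data trusted
   for levels, panel data for contrasts). The scalar solver is Brent's
   method to 1e-12 (verified against brute-force grid refinement); the
   full-grid build uses a damped vectorized Newton iteration on the same
   equation. The anchoring occupancy is the initial-distribution state mix
   by age and sex, held fixed over projection years — occupancy later
   depends on the table being built, and freezing the anchor avoids that
   circularity at negligible cost since the anchor only allocates a fixed
   population rate across states.

Step-2 odds ratios come from a 2-year observation interval and are applied
to annual probabilities unchanged; odds ratios are interval-stable to first
order and the calibration step absorbs any residual level error. If the two
cause-specific probabilities in a cell sum above one (extreme old-age
cells), they are rescaled proportionally, preserving the cause mix.

## Costs

All categories are evaluated on the (category, state, sex, single age) grid
once after fitting; the projection engine never refits. Amounts are
deflated to 2019 prices with the packaged deflator series
(`amount × index(2019)/index(source year)`).

- **Hospital**: OLS of annual cost on state flags, centred age, age², sex,
  fitted on the consenting (record-linked) subsample with HC1 robust
  standard errors (cost noise is skewed and heteroskedastic); predictions
  impute non-consenters. A consent share below 0.5 logs a warning.
  Negative grid predictions (possible at extreme extrapolated ages) clamp
  to zero.
- **Prescribing**: each reported medication code is matched to a formulary
  of annual net ingredient costs (unknown codes contribute a configurable
  default and log once); the per-person annual total then feeds the same
  two-part machinery as the social-care resources.
- **Two-part resources** (home care, cleaner, informal care): probit for
  any use × OLS for weekly amount among users; expected annual cost is
  `Φ(xβ) · max(0, xβ_OLS) · unit_cost · 52`.
- **Flat-rate resources**: participation probit × flat annual cost —
  residential care £39,156/yr (a 50:50 residential/nursing split is baked
  into that reference figure and not re-derived), daycare £7,280/yr (both
  2016/17 prices, deflated); cleaner hours are priced at 1.5 × the
  national living wage; informal hours at £7.76/h.
- **Calibration**: healthcare categories (hospital + prescribing) can be
  scaled by per-age-band factors external/modelled so band totals match an
  external series (covering costs the panel does not observe, e.g. primary
  care); factors are exact to 1e-9 and idempotent.

Costs per (state, age, sex) cell are held constant over projection years:
no technology, price or wage drift is modelled.

## Utilities and QALYs

Cell utility: age-band/sex population norm × disease multipliers (CVD 0.91,
CI 0.81, dementia 0.68, dementia superseding CI; CVD and dementia
multipliers compose multiplicatively) plus −0.042 × expected ADL count for
the state, clamped to [−0.594, 1]. The ADL decrement is applied additively
after the multiplicative disease adjustment — this matches how such a
decrement is estimated (a regression coefficient on the index scale); a
fully multiplicative reading is available via `adl_additive=False`. QALYs
for a year are the utility-weighted living counts; death states contribute
zero. Utility weights carry no probabilistic distribution in the PSA, so
QALY uncertainty is purely epidemiological.

## Projection and accounting

Deterministic expected-value cohort propagation (no microsimulation):
transition at current age, then age +1, entrants inserted at 35, deaths
accumulated at age at death. Age 100 is terminal — survivors stay 100 until
death. Person conservation is asserted every cycle to 1e-6 relative. No
half-cycle correction is applied; accounting is end-of-cycle annual.
Incidence/prevalence/mortality rates use the living population aged 35–100
at the start of the year as denominator, with incidence counting all flows
into CVD states from non-CVD states (prevalent cases are in the
denominator). Discounting runs from the first outcome-window year (2020);
cumulative results sum the discounted window years. England-scale
parameters are applied to the combined England-and-Wales-scale population.

## Scenario economics

Net monetary cost (scenario 1 − scenario 2) is
`Δtotal_costs + λ · (−ΔQALYs)`; the identity is exact by construction and
asserted per PSA draw. Excess disease costs use a counterfactual remap —
dementia states mapped to their FI-only counterparts, CVD states to their
non-CVD counterparts — so the comparison holds age, sex and other
disability fixed; totals divide by affected person-years for per-person
figures, and cost-of-illness tables report the same attribution by age
band (35–64, 65–79, 80–100).

**PSA.** Per draw: transition-logit coefficient vectors are sampled from
their estimated covariance; each cost category gets an independent
multiplier `2·B`, `B ~ Beta(α, α)` with α solved numerically so the central
95 % interval of the multiplier is [0.8, 1.2] (the interval, not the
parameterisation, is the specification; a shared draw across categories is
a config switch). Tables are rebuilt, both scenarios reprojected, and
empirical 2.5/97.5 percentiles reported — percentile rather than
normal-approximation intervals, since signed QALY differences are
asymmetric. Everything is deterministic given the seed.

## The synthetic data generator

The generator emulates a biennial longitudinal panel of adults sampled at
ages 50–89 (an ELSA-like design): states evolve under known logistic
transition models; cause-specific 2-year death draws precede a categorical
draw over permitted transitions (so per-kind incidence among survivors
equals the truth logit exactly); an 80 % consent flag gates hospital
costs; conditional hospital costs are lognormal around the linear truth
mean (nonnegative and skewed, stressing the OLS stage realistically);
social-care participation is probit-linked to match the estimation model;
panel mortality is piecewise-constant on the decadal age bands used by the
step-2 estimator, so the banded design is correctly specified and state
contrasts are recoverable — the population-rate series used for levels
remains continuous in age. ADL counts are truncated-Poisson per state
(≥ 1 in FI states), exposed as parameters.

Default generative parameters are chosen once to be epidemiologically
plausible for an England-and-Wales-scale population: annual CVD incidence
near 1,000 per 100,000 aged 35–100 with steep age gradients, historical
CVD mortality declining 4 %/yr and non-CVD 1 %/yr, a 33-million person
smooth age pyramid, 370,000 entrants per year. The demographic series are
smooth stand-ins, not official projections.

What the generator does **not** emulate: sampling weights, attrition,
proxy interviews, interval censoring (waves are exactly +2 years),
episode-level hospital structure, under-coverage of the institutionalised
population, and cohort effects in mortality. Passing recovery tests
therefore demonstrates correctness of the estimators under the model's own
assumptions, not robustness to these real-data features.

## Problem sizes and determinism

The packaged study conditions use a 20,000-person panel for the end-to-end
pipeline and 50,000 for the dedicated parameter-recovery checks; the
acceptance script runs a 200-draw PSA. All randomness flows through
explicit seeds (`numpy.random.default_rng`), and projections are
bit-reproducible.

## Known limitations

- The transition estimation ignores interval censoring and epoch pooling;
  probabilities are attributed to the observation interval directly.
- The log-linear mortality projection has no cohort term and no
  uncertainty; PSA epidemiological uncertainty enters through transition
  coefficients only.
- Residential-care fitting uses the panel as-is; population-representative
  re-weighting is a config hook, not a default.
- The excess-cost remap attributes to dementia only the increment over
  FI-only, so CVD and dementia excess costs overlap for people with both.
- Scenario differences at extreme old ages rest on extrapolated cost and
  transition regressions outside the panel's observed age range.
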