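"""Synthetic longitudinal ageing panel with known ground truth.

Emulates a biennial panel of adults aged 50+ (an ELSA-like design): health
states evolving under known logistic transition models with age, sex and
current-state effects; linked hospital costs carried only by a consenting
subsample; prescribed-medication lists with formulary unit costs; two-part
social-care hours with excess zeros; informal-care hours; institutional
residence; ADL counts and EQ-5D responses. Also produces stand-in
demographic series (initial state distribution, population by age, entrant
projections, historical cause-specific mortality) so the full projection
pipeline runs end to end without any external download.

Every generative parameter lives in :class:`GroundTruth`, so estimation
stages can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .states import (
    AGE_MAX,
    AGE_MIN,
    DEATH_STATES,
    LIVING_STATES,
    PERMITTED,
    HealthState,
    TransitionKind,
)

AGE_CENTER = 70  # ages are centred here in every linear predictor


class ConfigurationError(ValueError):
    """Invalid synthetic-panel configuration."""


@dataclass(frozen=True)
class FlagLogit:
    """Linear predictor on (centred age, male, morbidity flags) for a logit
    or probit link; the common covariate pattern of every model in the truth."""

    intercept: float
    age: float = 0.0
    sex: float = 0.0
    cvd: float = 0.0
    ci: float = 0.0
    fi: float = 0.0

    def linpred(self, age, male, state) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        male = np.asarray(male, dtype=float)
        if isinstance(state, HealthState):
            has_cvd, has_ci, has_fi = state.has_cvd, state.has_ci, state.has_fi
        else:
            state = np.asarray(state)
            has_cvd = np.isin(state, [s for s in HealthState if s.has_cvd])
            has_ci = np.isin(state, [s for s in HealthState if s.has_ci])
            has_fi = np.isin(state, [s for s in HealthState if s.has_fi])
        return (self.intercept + self.age * (age - AGE_CENTER) + self.sex * male
                + self.cvd * np.asarray(has_cvd, float)
                + self.ci * np.asarray(has_ci, float)
                + self.fi * np.asarray(has_fi, float))

    def prob(self, age, male, state) -> np.ndarray:
        return expit(self.linpred(age, male, state))


@dataclass(frozen=True)
class TwoPartTruth:
    """Generative two-part resource model: probit participation and a
    conditional amount (hours/week) with Gaussian noise, floored at zero."""

    participation: FlagLogit
    amount: FlagLogit
    amount_sd: float


def _default_transition_logits() -> dict[TransitionKind, FlagLogit]:
    # 2-year incidence scales chosen to give population rates of the order
    # observed for England & Wales adults 35-100 (annual CVD incidence near
    # 1,000-1,200 per 100,000, steep age gradients for impairment onset).
    return {
        TransitionKind.CVD_ONSET: FlagLogit(-3.9, age=0.055, sex=0.45, ci=0.30, fi=0.40),
        TransitionKind.CI_ONSET: FlagLogit(-4.1, age=0.095, sex=-0.10, cvd=0.35, fi=0.50),
        TransitionKind.FI_ONSET: FlagLogit(-3.3, age=0.105, sex=-0.20, cvd=0.50, ci=0.60),
        TransitionKind.FI_RECOVERY: FlagLogit(-1.3, age=-0.05, sex=0.10, cvd=-0.30),
    }


def _default_mortality_logits() -> dict[str, FlagLogit]:
    # 2-year cause-specific death; CVD raises CVD-death odds most, dementia
    # (ci+fi both set) raises non-CVD death.
    return {
        "CVD": FlagLogit(-5.6, age=0.100, sex=0.45, cvd=0.90, ci=0.25, fi=0.35),
        "NONCVD": FlagLogit(-4.4, age=0.105, sex=0.30, cvd=0.25, ci=0.45, fi=0.55),
    }


@dataclass(frozen=True)
class CostTruth:
    """Generative cost/resource-use parameters (amounts in GBP or hours/week)."""

    hospital_mean: FlagLogit = field(default_factory=lambda: FlagLogit(
        1400.0, age=35.0, sex=120.0, cvd=2000.0, ci=800.0, fi=1200.0))
    hospital_sigma_log: float = 0.8   # lognormal shape of costs given mean
    meds_rate: FlagLogit = field(default_factory=lambda: FlagLogit(
        1.2, age=0.02, cvd=1.0, ci=0.5, fi=0.5))  # Poisson rate of med count
    homecare: TwoPartTruth = field(default_factory=lambda: TwoPartTruth(
        FlagLogit(-1.9, age=0.030, sex=-0.15, cvd=0.2, ci=0.5, fi=0.9),
        FlagLogit(5.0, age=0.05, sex=-0.5, cvd=0.5, ci=2.0, fi=3.0), 3.0))
    cleaner: TwoPartTruth = field(default_factory=lambda: TwoPartTruth(
        FlagLogit(-2.0, age=0.035, sex=-0.20, cvd=0.1, ci=0.3, fi=0.6),
        FlagLogit(2.0, age=0.01, cvd=0.1, ci=0.3, fi=0.5), 1.0))
    informal: TwoPartTruth = field(default_factory=lambda: TwoPartTruth(
        FlagLogit(-1.5, age=0.030, sex=-0.10, cvd=0.3, ci=0.7, fi=1.0),
        FlagLogit(6.0, age=0.08, sex=-0.5, cvd=1.0, ci=4.0, fi=6.0), 4.0))
    daycare: FlagLogit = field(default_factory=lambda: FlagLogit(
        -2.6, age=0.030, sex=-0.10, cvd=0.1, ci=0.6, fi=0.7))
    residential: FlagLogit = field(default_factory=lambda: FlagLogit(
        -3.0, age=0.060, sex=-0.10, cvd=0.2, ci=0.8, fi=1.0))


#: EQ-5D population norms by age band and sex (index values typical of the
#: UK general population), disease multipliers, ADL decrement per limitation.
DEFAULT_NORMS = {
    (35, "F"): 0.90, (35, "M"): 0.92,
    (45, "F"): 0.84, (45, "M"): 0.86,
    (55, "F"): 0.79, (55, "M"): 0.81,
    (65, "F"): 0.77, (65, "M"): 0.79,
    (75, "F"): 0.72, (75, "M"): 0.74,
}


@dataclass(frozen=True)
class UtilityTruth:
    norms: dict = field(default_factory=lambda: dict(DEFAULT_NORMS))
    mult_cvd: float = 0.91
    mult_ci: float = 0.81
    mult_dementia: float = 0.68
    adl_decrement: float = -0.042


#: Mean ADL-limitation counts per state. States with functional impairment
#: have count >= 1 by construction (1 + truncated Poisson); others Poisson.
DEFAULT_ADL_MEANS = {
    HealthState.FREE: 0.05, HealthState.CVD: 0.10,
    HealthState.CI: 0.15, HealthState.FI: 1.8,
    HealthState.CVD_CI: 0.20, HealthState.CVD_FI: 2.2,
    HealthState.DEM: 2.8, HealthState.CVD_DEM: 3.2,
}


@dataclass(frozen=True)
class GroundTruth:
    """All generative parameters of the synthetic panel."""

    transition_logits: dict[TransitionKind, FlagLogit] = field(
        default_factory=_default_transition_logits)
    mortality_logits: dict[str, FlagLogit] = field(
        default_factory=_default_mortality_logits)
    costs: CostTruth = field(default_factory=CostTruth)
    utility: UtilityTruth = field(default_factory=UtilityTruth)
    adl_means: dict[HealthState, float] = field(
        default_factory=lambda: dict(DEFAULT_ADL_MEANS))
    consent_rate: float = 0.80

    def __post_init__(self):
        if not (0.0 < self.consent_rate <= 1.0):
            raise ConfigurationError(
                f"consent_rate must be in (0, 1], got {self.consent_rate}")


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic panel draw."""

    n_individuals: int = 20_000
    baseline_year: int = 2002
    n_waves: int = 6          # biennial waves
    seed: int = 0
    truth: GroundTruth = field(default_factory=GroundTruth)

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2 (need transitions)")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative int, got {self.seed!r}")


# ---------------------------------------------------------------------------
# formulary

#: Small synthetic formulary: code -> annual net ingredient cost (GBP).
FORMULARY = {f"BNF{i:02d}": cost for i, cost in enumerate(
    [8.0, 12.0, 15.5, 18.0, 22.0, 26.5, 30.0, 36.0, 42.0, 55.0,
     64.0, 78.0, 95.0, 110.0, 132.0, 155.0, 190.0, 230.0, 275.0, 320.0],
    start=1)}


# ---------------------------------------------------------------------------
# panel generation

def _draw_initial_states(rng: np.random.Generator, age: np.ndarray,
                         male: np.ndarray) -> np.ndarray:
    """Baseline states from independent age-graded flag prevalences."""
    p_cvd = expit(-3.3 + 0.060 * (age - AGE_CENTER) + 0.4 * male)
    p_ci = expit(-3.8 + 0.090 * (age - AGE_CENTER))
    p_fi = expit(-3.1 + 0.095 * (age - AGE_CENTER) - 0.2 * male)
    cvd = rng.random(age.size) < p_cvd
    ci = rng.random(age.size) < p_ci
    fi = rng.random(age.size) < p_fi
    return _state_from_flags(cvd, ci, fi)


def _state_from_flags(cvd, ci, fi) -> np.ndarray:
    lookup = np.empty((2, 2, 2), dtype=np.int64)
    for s in LIVING_STATES:
        lookup[int(s.has_cvd), int(s.has_ci), int(s.has_fi)] = int(s)
    return lookup[cvd.astype(int), ci.astype(int), fi.astype(int)]


_FLAG_STATES = {
    "cvd": np.array([int(s) for s in HealthState if s.has_cvd]),
    "ci": np.array([int(s) for s in HealthState if s.has_ci]),
    "fi": np.array([int(s) for s in HealthState if s.has_fi]),
}


def _flags_of(state: np.ndarray):
    return (np.isin(state, _FLAG_STATES["cvd"]),
            np.isin(state, _FLAG_STATES["ci"]),
            np.isin(state, _FLAG_STATES["fi"]))


def banded_age(age) -> np.ndarray:
    """Midpoint of the decadal mortality age bands (50-59, 60-69, 70-79,
    80+); the panel's generative death model is piecewise-constant on these
    bands so the banded estimation design is correctly specified."""
    age = np.asarray(age, float)
    mid = np.clip((age // 10) * 10 + 4.5, 54.5, 84.5)
    return mid


def _step_states(rng: np.random.Generator, state: np.ndarray, age: np.ndarray,
                 male: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """One biennial step: cause-specific death first, then at most one
    incident transition among those surviving, drawn categorically."""
    n = state.size
    new = state.copy()
    alive = ~np.isin(state, [int(s) for s in DEATH_STATES])

    age_mort = banded_age(age)
    q_cvd = truth.mortality_logits["CVD"].prob(age_mort, male, state)
    q_non = truth.mortality_logits["NONCVD"].prob(age_mort, male, state)
    u = rng.random(n)
    died_cvd = alive & (u < q_cvd)
    died_non = alive & ~died_cvd & (u < q_cvd + q_non)
    new[died_cvd] = int(HealthState.DEATH_CVD)
    new[died_non] = int(HealthState.DEATH_NONCVD)
    moved = died_cvd | died_non

    # transition probabilities for each kind, zero where not permitted
    probs = np.zeros((len(TransitionKind), n))
    targets = np.zeros((len(TransitionKind), n), dtype=np.int64)
    for k, kind in enumerate(TransitionKind):
        logit = truth.transition_logits[kind]
        p = logit.prob(age, male, state)
        allowed = np.zeros(n, dtype=bool)
        tgt = np.zeros(n, dtype=np.int64)
        for s in LIVING_STATES:
            if kind in PERMITTED[s]:
                mask = state == int(s)
                allowed |= mask
                tgt[mask] = int(PERMITTED[s][kind])
        probs[k] = np.where(allowed, p, 0.0)
        targets[k] = tgt

    # categorical draw over kinds + stay, among survivors
    survivors = alive & ~moved
    cum = np.cumsum(probs, axis=0)
    total = cum[-1]
    scale = np.where(total > 1.0, total, 1.0)  # guard: renormalize if >1
    v = rng.random(n) * scale
    chosen = np.full(n, -1, dtype=np.int64)
    prev = np.zeros(n)
    for k in range(len(TransitionKind)):
        hit = survivors & (chosen < 0) & (v >= prev) & (v < cum[k])
        chosen[hit] = k
        prev = cum[k]
    for k in range(len(TransitionKind)):
        mask = chosen == k
        new[mask] = targets[k][mask]
    return new


def _draw_adl(rng: np.random.Generator, state: np.ndarray,
              adl_means: dict[HealthState, float]) -> np.ndarray:
    adl = np.zeros(state.size, dtype=np.int64)
    for s in LIVING_STATES:
        mask = state == int(s)
        if not mask.any():
            continue
        mean = adl_means[s]
        if s.has_fi:  # functional impairment implies at least one limitation
            adl[mask] = 1 + rng.poisson(max(mean - 1.0, 0.0), mask.sum())
        else:
            adl[mask] = rng.poisson(mean, mask.sum())
    return adl


def _two_part_draw(rng, tp: TwoPartTruth, age, male, state):
    # participation is probit-linked, matching the estimation model
    use = rng.random(age.size) < norm.cdf(tp.participation.linpred(age, male, state))
    amt = tp.amount.linpred(age, male, state) + rng.normal(0, tp.amount_sd, age.size)
    return np.where(use, np.maximum(amt, 0.1), 0.0)


def _utility_truth(age, male, state, adl, ut: UtilityTruth) -> np.ndarray:
    band = np.minimum((np.asarray(age, float) // 10) * 10 + 5, 75)
    band = np.maximum(((band - 35) // 10 * 10 + 35).astype(int), 35)
    u0 = np.array([ut.norms[(b, "M" if m else "F")]
                   for b, m in zip(band, np.asarray(male, bool))])
    cvd, ci, fi = _flags_of(np.asarray(state))
    mult = np.ones(u0.size)
    mult *= np.where(cvd, ut.mult_cvd, 1.0)
    dem = ci & fi
    mult *= np.where(dem, ut.mult_dementia, np.where(ci, ut.mult_ci, 1.0))
    u = u0 * mult + ut.adl_decrement * np.asarray(adl, float)
    return np.clip(u, -0.594, 1.0)


def generate_panel(config: PanelConfig) -> pd.DataFrame:
    """Generate the biennial panel as a tidy DataFrame, one row per
    (person, wave) observation; dead individuals contribute a final row in
    their death state and then leave the panel.

    Reproducible bit-for-bit for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    n = config.n_individuals

    age = rng.integers(50, 90, n).astype(float)
    male = (rng.random(n) < 0.5).astype(int)
    state = _draw_initial_states(rng, age, male)
    consented = rng.random(n) < truth.consent_rate
    pid = np.arange(n)

    rows = []
    present = np.ones(n, dtype=bool)  # in the panel (not yet recorded dead)
    for wave in range(config.n_waves):
        year = config.baseline_year + 2 * wave
        idx = np.flatnonzero(present)
        a, m, s = age[idx], male[idx], state[idx]
        alive = ~np.isin(s, [int(d) for d in DEATH_STATES])
        adl = _draw_adl(rng, s, truth.adl_means)
        adl[~alive] = 0

        hosp_mean = np.maximum(truth.costs.hospital_mean.linpred(a, m, s), 50.0)
        sig = truth.costs.hospital_sigma_log
        hosp = rng.lognormal(np.log(hosp_mean) - sig**2 / 2, sig, idx.size)
        hosp = np.where(alive & consented[idx], hosp, np.nan)

        n_meds = rng.poisson(np.maximum(truth.costs.meds_rate.linpred(a, m, s), 0.0))
        n_meds[~alive] = 0
        codes = np.array(list(FORMULARY))
        flat = codes[rng.integers(0, codes.size, int(n_meds.sum()))]
        med_lists = [list(chunk) for chunk in
                     np.split(flat, np.cumsum(n_meds)[:-1])]

        homecare = _two_part_draw(rng, truth.costs.homecare, a, m, s)
        cleaner = _two_part_draw(rng, truth.costs.cleaner, a, m, s)
        informal = _two_part_draw(rng, truth.costs.informal, a, m, s)
        daycare = rng.random(idx.size) < norm.cdf(
            truth.costs.daycare.linpred(a, m, s))
        instit = rng.random(idx.size) < norm.cdf(
            truth.costs.residential.linpred(a, m, s))
        for arr in (homecare, cleaner, informal):
            arr[~alive] = 0.0
        daycare &= alive
        instit &= alive

        eq5d = _utility_truth(a, m, s, adl, truth.utility)
        eq5d = np.where(alive, eq5d, np.nan)

        rows.append(pd.DataFrame({
            "pid": pid[idx], "wave": wave, "year": year,
            "age": a.astype(int), "male": m, "state": s,
            "adl_count": adl, "consented": consented[idx],
            "hospital_cost": hosp, "med_list": med_lists,
            "homecare_hours": homecare, "cleaner_hours": cleaner,
            "informal_hours": informal, "daycare_use": daycare.astype(int),
            "in_institution": instit.astype(int), "eq5d": eq5d,
        }))

        # dead this wave: recorded once, then dropped
        present[idx[~alive]] = False
        if wave < config.n_waves - 1:
            state = _step_states(rng, state, age, male, truth)
            age = age + 2.0

    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# stand-in demography

def occupancy_by_age(truth: GroundTruth, reference_year: int = 2011
                     ) -> np.ndarray:
    """Deterministic living-state occupancy shares by age and sex implied by
    the ground truth, from cohort propagation starting disease-free at 35.

    Returns array of shape (n_ages, 2 sexes, n_living) with rows summing to 1.
    """
    n_ages = AGE_MAX - AGE_MIN + 1
    occ = np.zeros((n_ages, 2, len(LIVING_STATES)))
    for sex_idx, male in enumerate((0, 1)):
        share = np.zeros(len(LIVING_STATES))
        share[int(HealthState.FREE)] = 1.0
        occ[0, sex_idx] = share
        for ai, age in enumerate(range(AGE_MIN, AGE_MAX)):
            nxt = np.zeros_like(share)
            for s in LIVING_STATES:
                mass = share[int(s)]
                if mass == 0:
                    continue
                # annualized incident probabilities from the 2-year truth
                p1 = {}
                for kind, target in PERMITTED[s].items():
                    p2 = float(truth.transition_logits[kind].prob(age, male, s))
                    p1[target] = 1.0 - np.sqrt(1.0 - p2)
                q2 = (float(truth.mortality_logits["CVD"].prob(age, male, s))
                      + float(truth.mortality_logits["NONCVD"].prob(age, male, s)))
                surv1 = np.sqrt(max(1.0 - q2, 0.0))
                stay = max(1.0 - sum(p1.values()), 0.0)
                for target, p in p1.items():
                    nxt[int(target)] += mass * surv1 * p
                nxt[int(s)] += mass * surv1 * stay
            total = nxt.sum()
            occ[ai + 1, sex_idx] = nxt / total if total > 0 else 0.0
    return occ


def population_by_age(total_population: float = 33_000_000.0) -> pd.DataFrame:
    """Smooth stand-in age pyramid for ages 35-100, both sexes, normalised to
    ``total_population`` persons (England & Wales adults 35+ scale)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    base = np.exp(-0.012 * (ages - AGE_MIN)) * np.exp(
        -np.maximum(ages - 78, 0.0) ** 2 / 350.0)  # old-age tail thinning
    rows = []
    for sex in ("F", "M"):
        w = base * (1.03 if sex == "F" else 0.97)
        rows.append(pd.DataFrame({"sex": sex, "age": ages, "count": w}))
    df = pd.concat(rows, ignore_index=True)
    df["count"] = df["count"] / df["count"].sum() * total_population
    return df


def initial_distribution(truth: GroundTruth, year: int = 2011,
                         total_population: float = 33_000_000.0) -> pd.DataFrame:
    """Initial (year-2011) population counts by sex, age and living state."""
    pop = population_by_age(total_population)
    occ = occupancy_by_age(truth, year)
    rows = []
    for _, r in pop.iterrows():
        ai = int(r["age"]) - AGE_MIN
        si = 0 if r["sex"] == "F" else 1
        for s in LIVING_STATES:
            rows.append((year, r["sex"], int(r["age"]), s.name,
                         r["count"] * occ[ai, si, int(s)]))
    return pd.DataFrame(rows, columns=["year", "sex", "age", "state", "count"])


def entrant_projections(first_year: int = 2011, last_year: int = 2030,
                        base_entrants: float = 370_000.0,
                        annual_growth: float = 0.003) -> pd.DataFrame:
    """Projected new 35-year-old entrants per sex and year (all disease-free)."""
    rows = []
    for year in range(first_year, last_year + 1):
        n = base_entrants * (1 + annual_growth) ** (year - first_year)
        for sex in ("F", "M"):
            rows.append((year, sex, n * (0.97 / 2 if sex == "M" else 1.03 / 2) * 2))
    return pd.DataFrame(rows, columns=["year", "sex", "entrants"])


def historical_mortality(first_year: int = 1990, last_year: int = 2016,
                         cvd_decline: float = -0.04,
                         noncvd_decline: float = -0.01) -> pd.DataFrame:
    """Stand-in historical cause-specific mortality rates in 5-year age bands.

    Gompertz in age; log-linear calendar decline per cause (CVD mortality
    falling ~4%/yr as over 1991-2011 in England & Wales, non-CVD ~1%/yr).
    """
    bands = [(a, min(a + 4, AGE_MAX)) for a in range(AGE_MIN, AGE_MAX + 1, 5)]
    base = {"CVD": (-5.8, 0.095), "NONCVD": (-4.6, 0.100)}  # log rate at 70, slope
    decline = {"CVD": cvd_decline, "NONCVD": noncvd_decline}
    rows = []
    for cause, (b0, b_age) in base.items():
        for lo, hi in bands:
            mid = (lo + hi) / 2
            for sex, sex_eff in (("F", 0.0), ("M", 0.35)):
                for year in range(first_year, last_year + 1):
                    log_rate = (b0 + b_age * (mid - AGE_CENTER) + sex_eff
                                + np.log1p(decline[cause]) * (year - 2011))
                    rows.append((cause, sex, f"{lo}-{hi}", mid, year,
                                 float(np.exp(log_rate))))
    return pd.DataFrame(rows, columns=["cause", "sex", "age_band",
                                       "age_mid", "year", "rate"])


def deflator_series() -> pd.DataFrame:
    """Stand-in GDP deflator index (2019 = 100), ~2%/yr price growth."""
    years = np.arange(2005, 2021)
    index = 100.0 * 1.02 ** (years - 2019.0)
    return pd.DataFrame({"year": years, "index": index})


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs feeding the cost model, with their native price years."""

    informal_per_hour: float = 7.76        # GBP/h, 2019 prices
    residential_per_year: float = 39_156.0  # GBP/yr (PSSRU-style reference)
    residential_price_year: int = 2017
    daycare_per_year: float = 7_280.0      # GBP/yr, 2016/17 prices
    daycare_price_year: int = 2017
    living_wage_per_hour: float = 8.21     # national living wage, 2019
    cleaner_multiplier: float = 1.5        # cleaner = 1.5 x living wage
    homecare_per_hour: float = 26.0        # GBP/h, 2016/17 prices
    homecare_price_year: int = 2017

    @property
    def cleaner_per_hour(self) -> float:
        return self.cleaner_multiplier * self.living_wage_per_hour


def export_supplementary_layout(out_dir, truth: GroundTruth | None = None,
                                total_population: float = 33_000_000.0,
                                year: int = 2011) -> dict[str, str]:
    """Write the demographic bundle (initial state distribution, initial
    population size, entrant projections) as CSVs in the package's canonical
    long-format schemas. Returns a name -> path mapping."""
    import os

    from . import io as ccio

    truth = truth or GroundTruth()
    os.makedirs(out_dir, exist_ok=True)
    dist = initial_distribution(truth, year, total_population)
    pop = population_by_age(total_population)
    ent = entrant_projections(first_year=year)

    _validate_demography(dist, pop)

    paths = {}
    for name, df, writer in [
        ("initial_distribution", dist, ccio.write_initial_distribution),
        ("initial_population", pop, ccio.write_initial_population),
        ("population_projections", ent, ccio.write_entrants),
    ]:
        path = os.path.join(out_dir, f"{name}.csv")
        writer(df, path)
        paths[name] = path
    return paths


class DemographyValidationError(ValueError):
    """Demography bundle fails coverage/positivity checks."""


def _validate_demography(dist: pd.DataFrame, pop: pd.DataFrame) -> None:
    missing = []
    have = set(zip(pop["sex"], pop["age"]))
    for sex in ("F", "M"):
        for age in range(AGE_MIN, AGE_MAX + 1):
            if (sex, age) not in have:
                missing.append((sex, age))
    if missing:
        raise DemographyValidationError(
            f"missing (sex, age) cells in population table: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    if not (pop["count"] > 0).any() or dist["count"].sum() <= 0:
        raise DemographyValidationError("population is zero everywhere")
    if (dist["count"] < 0).any() or (pop["count"] < 0).any():
        raise DemographyValidationError("negative population counts")
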