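"""Three-step mortality model.

Step 1 projects population cause-specific (CVD vs non-CVD) death
probabilities forward by a deterministic log-linear age-period fit to
historical rates in 5-year age bands, interpolated to single year of age.
Step 2 estimates how death odds vary across model health states from panel
data (a reference logistic with sex, age group and their interaction, and a
second adding state indicators). Step 3 calibrates: for every
(cause, age, sex, year) cell an additive logit offset is solved so the
state-occupancy-weighted mean of the state-specific death probabilities
reproduces the population rate exactly — population-level data are trusted
for levels, panel data for state contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit

from .states import (
    AGE_MAX,
    AGE_MIN,
    DEATH_STATES,
    LIVING_STATES,
    SEXES,
    HealthState,
)

CAUSES = ("CVD", "NONCVD")

#: Age groups used for the panel mortality fit.
AGE_GROUPS = ((50, 59), (60, 69), (70, 79), (80, 89))


class MortalityInputError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# step 1: population projection

@dataclass
class MortalityRates:
    """Annual population death probabilities q[cause, sex, age, year]."""

    years: list[int]
    q: np.ndarray  # shape (2 causes, 2 sexes, n_ages, n_years)

    def rate(self, cause: str, sex: str, year: int) -> np.ndarray:
        """Rates over ages 35..100 for one (cause, sex, year)."""
        return self.q[CAUSES.index(cause), SEXES.index(sex), :,
                      self.years.index(year)]


def project_population_mortality(historical: pd.DataFrame,
                                 horizon: int = 2030) -> MortalityRates:
    """Log-linear age-period projection of cause-specific mortality.

    ``historical`` columns: cause, sex, age_band ("lo-hi"), age_mid, year,
    rate. Per (cause, age band, sex) a straight line is fitted to log rate
    against calendar year and extrapolated to ``horizon``; band projections
    are interpolated to single year of age piecewise-linearly on the log
    scale at band midpoints, with constant extrapolation beyond the outer
    midpoints.
    """
    req = {"cause", "sex", "age_mid", "year", "rate"}
    if not req.issubset(historical.columns):
        raise MortalityInputError(f"historical table needs columns {sorted(req)}")
    if (historical["rate"] <= 0).any():
        raise MortalityInputError("non-positive historical rates")

    first = int(historical["year"].min())
    years = list(range(first, horizon + 1))
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    q = np.zeros((len(CAUSES), len(SEXES), ages.size, len(years)))

    for ci, cause in enumerate(CAUSES):
        for si, sex in enumerate(SEXES):
            sub = historical[(historical["cause"] == cause)
                             & (historical["sex"] == sex)]
            if sub.empty:
                raise MortalityInputError(f"no rates for ({cause}, {sex})")
            mids, band_logs = [], []
            for mid, grp in sub.groupby("age_mid"):
                if grp["year"].nunique() < 10:
                    raise MortalityInputError(
                        f"need >= 10 historical years for ({cause}, {sex}, "
                        f"band mid {mid}); have {grp['year'].nunique()}")
                X = sm.add_constant(grp["year"].astype(float))
                fit = sm.OLS(np.log(grp["rate"].to_numpy()), X).fit()
                a, b = fit.params
                mids.append(float(mid))
                band_logs.append(a + b * np.asarray(years, float))
            order = np.argsort(mids)
            mids = np.asarray(mids)[order]
            band_logs = np.asarray(band_logs)[order]  # (n_bands, n_years)
            for yi in range(len(years)):
                log_single = np.interp(ages, mids, band_logs[:, yi])
                q[ci, si, :, yi] = np.clip(np.exp(log_single), 1e-12, 1 - 1e-9)
    return MortalityRates(years, q)


# ---------------------------------------------------------------------------
# step 2: state contrasts from panel data

@dataclass
class StateMortalityModel:
    """Fitted death logits: reference (demographics only) and full
    (demographics + state indicators), per cause; state odds multipliers are
    exp of the state-flag coefficients of the full model."""

    reference_params: dict[str, pd.Series]
    full_params: dict[str, pd.Series]
    vcov: dict[str, pd.DataFrame]
    interval_years: int = 2

    def odds_multiplier(self, cause: str, state: HealthState) -> float:
        p = self.full_params[cause]
        lo = (p.get("has_cvd", 0.0) * state.has_cvd
              + p.get("has_ci", 0.0) * state.has_ci
              + p.get("has_fi", 0.0) * state.has_fi)
        return float(np.exp(lo))

    def odds_multipliers(self, cause: str) -> dict[HealthState, float]:
        return {s: self.odds_multiplier(cause, s) for s in LIVING_STATES}


def _death_design(df: pd.DataFrame, with_state: bool) -> tuple[pd.DataFrame, list[str]]:
    grp = np.zeros(len(df), dtype=int)
    for gi, (lo, hi) in enumerate(AGE_GROUPS):
        grp[(df["age"] >= lo) & (df["age"] <= hi)] = gi
    grp[df["age"] > AGE_GROUPS[-1][1]] = len(AGE_GROUPS) - 1  # 90+ pooled with 80-89
    X = {"const": np.ones(len(df)), "male": df["male"].astype(float).to_numpy()}
    for gi in range(1, len(AGE_GROUPS)):
        X[f"ageg{gi}"] = (grp == gi).astype(float)
        X[f"male_x_ageg{gi}"] = X[f"ageg{gi}"] * X["male"]
    if with_state:
        for flag, idx in (("has_cvd", _CVD_IDX), ("has_ci", _CI_IDX),
                          ("has_fi", _FI_IDX)):
            X[flag] = df["state"].isin(idx).astype(float).to_numpy()
    Xf = pd.DataFrame(X)
    return Xf, list(Xf.columns)


_CVD_IDX = [int(s) for s in HealthState if s.has_cvd]
_CI_IDX = [int(s) for s in HealthState if s.has_ci]
_FI_IDX = [int(s) for s in HealthState if s.has_fi]


def fit_state_mortality(panel: pd.DataFrame) -> StateMortalityModel:
    """Fit the step-2 death logits on wave-to-wave panel observations.

    Outcome per cause: death from that cause by the next wave (deaths from
    the competing cause count as non-events). Raises
    :class:`MortalityInputError` naming the stratum when a (sex, age-group)
    stratum has no deaths at all.
    """
    from .transitions import _panel_transitions

    obs = _panel_transitions(panel)
    obs = obs[~obs["state"].isin([int(s) for s in DEATH_STATES])]
    if obs.empty:
        raise MortalityInputError("panel has no at-risk observations")

    died = {"CVD": (obs["to_state"] == int(HealthState.DEATH_CVD)).astype(int),
            "NONCVD": (obs["to_state"] == int(HealthState.DEATH_NONCVD)).astype(int)}
    any_death = (died["CVD"] | died["NONCVD"]).to_numpy()
    for male in (0, 1):
        for lo, hi in AGE_GROUPS:
            m = ((obs["male"] == male) & (obs["age"] >= lo)
                 & (obs["age"] <= hi)).to_numpy()
            if m.any() and any_death[m].sum() == 0:
                raise MortalityInputError(
                    f"no deaths in stratum sex={'M' if male else 'F'} "
                    f"age {lo}-{hi}; cannot estimate state contrasts")

    reference, full, vcovs = {}, {}, {}
    for cause in CAUSES:
        y = died[cause].to_numpy()
        if y.sum() == 0:
            raise MortalityInputError(f"no {cause} deaths in the panel")
        for with_state, store in ((False, reference), (True, full)):
            X, names = _death_design(obs, with_state)
            keep = ["const"] + [c for c in names if c != "const"
                                and X[c].nunique() > 1]
            X, names = X[keep], keep
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise MortalityInputError(f"{cause}: non-finite death logit")
            store[cause] = pd.Series(res.params, index=names)
            if with_state:
                vcovs[cause] = pd.DataFrame(res.cov_params(), index=names,
                                            columns=names)
    return StateMortalityModel(reference, full, vcovs)


# ---------------------------------------------------------------------------
# step 3: calibration

def calibrate_state_mortality(q_pop: float,
                              state_odds: dict[HealthState, float],
                              occupancy: dict[HealthState, float],
                              tol: float = 1e-12) -> dict[HealthState, float]:
    """Solve the additive logit offset k so that the occupancy-weighted mean
    of q_s = expit(logit(q_pop) + k + log(odds_s)) equals q_pop.

    Preserves the fitted state contrasts (odds ratios) exactly while
    reproducing the population rate exactly.
    """
    if not (0.0 < q_pop < 1.0):
        raise CalibrationError(f"q_pop must be in (0,1), got {q_pop}")
    occ = np.array([occupancy.get(s, 0.0) for s in state_odds])
    if occ.sum() <= 0:
        raise CalibrationError("occupancy sums to zero")
    occ = occ / occ.sum()
    log_or = np.log(np.array([state_odds[s] for s in state_odds]))
    base = logit(q_pop)

    def f(k):
        return float(occ @ expit(base + k + log_or) - q_pop)

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"no root in [{lo},{hi}] for q_pop={q_pop}, odds={state_odds}")
    k = brentq(f, lo, hi, xtol=tol)
    return {s: float(expit(base + k + lo_or))
            for s, lo_or in zip(state_odds, log_or)}


def _newton_offsets(base_logit: np.ndarray, log_or: np.ndarray,
                    occ: np.ndarray, q_pop: np.ndarray,
                    iters: int = 60) -> np.ndarray:
    """Vectorized Newton solve of the calibration offset over many cells.

    base_logit, q_pop: shape (...); log_or, occ: shape (..., n_states).
    The mixture is strictly increasing in k, so Newton from 0 with a damped
    fallback converges for all admissible inputs.
    """
    k = np.zeros_like(base_logit)
    for _ in range(iters):
        p = expit(base_logit[..., None] + k[..., None] + log_or)
        f = (occ * p).sum(-1) - q_pop
        fp = (occ * p * (1 - p)).sum(-1)
        step = f / np.maximum(fp, 1e-300)
        k = k - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(f)) < 1e-13:
            break
    return k


@dataclass
class StateMortalityTable:
    """Calibrated annual per-state death probabilities over the projection
    grid; the object `build_transition_table` consumes."""

    years: list[int]
    #: shape (2 causes, 2 sexes, n_ages, n_years, n_living_states)
    q_state: np.ndarray

    def q(self, cause: str, state: HealthState, sex: str, year: int) -> np.ndarray:
        return self.q_state[CAUSES.index(cause), SEXES.index(sex), :,
                            self.years.index(year), int(state)]


def build_state_mortality_table(rates: MortalityRates,
                                model: StateMortalityModel | None,
                                occupancy: np.ndarray,
                                years=None,
                                annualize_odds: bool = True) -> StateMortalityTable:
    """Calibrate per-state death probabilities for every grid cell.

    ``occupancy`` has shape (n_ages, 2 sexes, n_living) and gives the state
    mixture used to anchor the population rate (held fixed across years).
    ``model`` may be None, in which case all states share the population rate.
    Step-2 odds ratios come from a 2-year interval; with ``annualize_odds``
    they are applied unchanged to annual probabilities (odds ratios are
    interval-stable to first order; documented choice).
    """
    years = list(years) if years is not None else list(rates.years)
    n_ages = AGE_MAX - AGE_MIN + 1
    qs = np.zeros((len(CAUSES), len(SEXES), n_ages, len(years),
                   len(LIVING_STATES)))
    occ = occupancy / np.maximum(occupancy.sum(-1, keepdims=True), 1e-300)

    for ci, cause in enumerate(CAUSES):
        if model is None:
            log_or = np.zeros(len(LIVING_STATES))
        else:
            log_or = np.log([model.odds_multiplier(cause, s)
                             for s in LIVING_STATES])
        for si in range(len(SEXES)):
            # q_pop over (age, year)
            yidx = [rates.years.index(y) for y in years]
            qp = rates.q[ci, si][:, yidx]                       # (ages, years)
            base = logit(np.clip(qp, 1e-12, 1 - 1e-12))
            occ_cell = occ[:, si, :][:, None, :]                # (ages,1,nliv)
            occ_b = np.broadcast_to(occ_cell, (n_ages, len(years),
                                               len(LIVING_STATES)))
            lor_b = np.broadcast_to(log_or, occ_b.shape)
            k = _newton_offsets(base, lor_b, occ_b, qp)
            qs[ci, si] = expit(base[..., None] + k[..., None] + lor_b)
    return StateMortalityTable(years, qs)


class ZeroMortality:
    """Mortality stub assigning zero death probability everywhere (testing)."""

    def q(self, cause, state, sex, year):
        return np.zeros(AGE_MAX - AGE_MIN + 1)
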