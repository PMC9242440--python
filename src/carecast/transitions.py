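"""Transition-probability estimation and scenario table assembly.

Two-year incidence of CVD, cognitive impairment, functional impairment and
recovery from functional impairment is estimated by logistic regression on
panel data with age, sex and current-state indicators as covariates. The
fitted two-year probabilities are annualized by the complement-root under
independent competing risks, calendar trends are applied to incidence
(the CVD-plateau vs CVD-fall scenarios and a secular decline in cognitive
impairment), state-specific death probabilities are inserted, and the result
is a full annual transition table over ages 35-100, both sexes and the
projection years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .states import (
    AGE_MAX,
    AGE_MIN,
    DEATH_STATES,
    LIVING_STATES,
    N_STATES,
    PERMITTED,
    RISK_SETS,
    SEXES,
    HealthState,
    TransitionKind,
)
from .synthetic import AGE_CENTER

log = logging.getLogger(__name__)

REFERENCE_YEAR = 2011          # scenarios diverge after this calendar year
CI_ANNUAL_DECLINE = 0.027      # secular fall in cognitive-impairment incidence


class EstimationError(RuntimeError):
    """Logistic estimation failed (separation, empty risk set, no events)."""


class AssemblyError(RuntimeError):
    """Transition-table assembly found coverage gaps."""


#: Covariate columns used by each transition-kind regression: always
#: intercept, centred age and sex; state flags only where the risk set varies
#: on that flag.
def _covariate_names(kind: TransitionKind) -> list[str]:
    names = ["const", "age_c", "male"]
    risk = RISK_SETS[kind]
    for flag in ("has_cvd", "has_ci", "has_fi"):
        if len({getattr(s, flag) for s in risk}) > 1:
            names.append(flag)
    return names


@dataclass
class TransitionLogit:
    """A fitted (or ground-truth) two-year incidence logit."""

    kind: TransitionKind
    params: pd.Series                  # indexed by covariate names
    vcov: pd.DataFrame | None = None   # coefficient covariance (None = exact)
    interval_years: int = 2

    def design_row(self, age: float, male: int, state: HealthState) -> np.ndarray:
        vals = {"const": 1.0, "age_c": float(age) - AGE_CENTER,
                "male": float(male),
                "has_cvd": float(state.has_cvd),
                "has_ci": float(state.has_ci),
                "has_fi": float(state.has_fi)}
        return np.array([vals[c] for c in self.params.index])

    def prob2(self, age, male, state: HealthState) -> float:
        """Two-year incidence probability at the given covariates."""
        return float(expit(self.design_row(age, male, state) @ self.params.values))

    def prob2_ages(self, ages: np.ndarray, male: int, state: HealthState) -> np.ndarray:
        x0 = self.design_row(AGE_CENTER, male, state)
        eta = x0 @ self.params.values
        if "age_c" in self.params.index:
            eta = eta + self.params["age_c"] * (np.asarray(ages, float) - AGE_CENTER)
        return expit(eta)

    def perturbed(self, rng: np.random.Generator) -> "TransitionLogit":
        """Draw a coefficient vector from N(params, vcov) for the PSA."""
        if self.vcov is None:
            return self
        try:
            draw = rng.multivariate_normal(self.params.values,
                                           self.vcov.values, method="cholesky")
        except np.linalg.LinAlgError:
            draw = rng.multivariate_normal(self.params.values,
                                           self.vcov.values, method="svd")
        return TransitionLogit(self.kind, pd.Series(draw, index=self.params.index),
                               vcov=self.vcov, interval_years=self.interval_years)


def _panel_transitions(panel: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive waves per person into (from, to) observations."""
    panel = panel.sort_values(["pid", "wave"])
    cur = panel[["pid", "wave", "age", "male", "state"]]
    nxt = cur.copy()
    nxt["wave"] -= 1
    merged = cur.merge(nxt, on=["pid", "wave"], suffixes=("", "_next"))
    merged = merged.rename(columns={"state_next": "to_state"})
    return merged[["pid", "age", "male", "state", "to_state"]]


def fit_transition_logits(panel: pd.DataFrame,
                          kinds=None) -> dict[TransitionKind, TransitionLogit]:
    """Fit one two-year incidence logit per permitted transition kind.

    The risk set for each kind is every living-state observation from which
    that transition is permitted; the outcome is whether the next-wave state
    reflects that incident event. Observations dying before the next wave are
    excluded (incidence conditional on survival, matching how the annual
    table composes survival with conditional movement).
    """
    obs = _panel_transitions(panel)
    dead_next = obs["to_state"].isin([int(s) for s in DEATH_STATES])
    obs = obs[~dead_next]

    out: dict[TransitionKind, TransitionLogit] = {}
    for kind in (kinds if kinds is not None else TransitionKind):
        risk_states = [int(s) for s in RISK_SETS[kind]]
        sub = obs[obs["state"].isin(risk_states)]
        if len(sub) == 0:
            raise EstimationError(f"{kind.value}: empty risk set")
        target = np.zeros(len(sub), dtype=int)
        for s in RISK_SETS[kind]:
            tgt = int(PERMITTED[s][kind])
            target |= ((sub["state"] == int(s)) & (sub["to_state"] == tgt)).to_numpy()
        n_events = int(target.sum())
        if n_events == 0 or n_events == len(sub):
            raise EstimationError(
                f"{kind.value}: degenerate outcome ({n_events} events in "
                f"{len(sub)} at-risk observations); intercept unbounded")

        names = _covariate_names(kind)
        X = pd.DataFrame({
            "const": 1.0,
            "age_c": sub["age"].astype(float) - AGE_CENTER,
            "male": sub["male"].astype(float),
            "has_cvd": sub["state"].isin(_FLAG_IDX["has_cvd"]).astype(float),
            "has_ci": sub["state"].isin(_FLAG_IDX["has_ci"]).astype(float),
            "has_fi": sub["state"].isin(_FLAG_IDX["has_fi"]).astype(float),
        })[names]
        # zero-variance covariates (e.g. single covariate pattern) collapse
        # the fit to the remaining terms rather than a singular design
        keep = ["const"] + [c for c in names[1:] if X[c].nunique() > 1]
        X = X[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(target, X).fit(disp=0, maxiter=200)
            except Exception as exc:  # perfect separation raises in sm
                raise EstimationError(f"{kind.value}: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise EstimationError(f"{kind.value}: non-finite coefficients")
        out[kind] = TransitionLogit(kind, pd.Series(res.params.to_numpy(), index=keep),
                                    vcov=pd.DataFrame(res.cov_params().to_numpy(),
                                                      index=keep, columns=keep))
    return out


_FLAG_IDX = {
    "has_cvd": [int(s) for s in HealthState if s.has_cvd],
    "has_ci": [int(s) for s in HealthState if s.has_ci],
    "has_fi": [int(s) for s in HealthState if s.has_fi],
}


def logits_from_truth(truth) -> dict[TransitionKind, TransitionLogit]:
    """Exact TransitionLogit objects from a synthetic GroundTruth (no vcov)."""
    out = {}
    for kind, fl in truth.transition_logits.items():
        names = _covariate_names(kind)
        vals = {"const": fl.intercept, "age_c": fl.age, "male": fl.sex,
                "has_cvd": fl.cvd, "has_ci": fl.ci, "has_fi": fl.fi}
        out[kind] = TransitionLogit(kind, pd.Series({n: vals[n] for n in names}))
    return out


# ---------------------------------------------------------------------------
# annualization

def annualize(p2: np.ndarray) -> np.ndarray:
    """Convert two-year transition probabilities to one-year under
    independent competing risks: p1 = 1 - (1 - p2)^(1/2), elementwise."""
    p2 = np.asarray(p2, dtype=float)
    if np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("two-year probabilities must lie in [0, 1]")
    return 1.0 - np.sqrt(1.0 - p2)


def annualize_row(p2_offdiag: dict, renorm_warn: bool = True):
    """Annualize a row of off-diagonal two-year probabilities and fill the
    stay probability. Returns (one-year dict, stay probability)."""
    p1 = {k: float(annualize(v)) for k, v in p2_offdiag.items()}
    stay = 1.0 - sum(p1.values())
    if stay < 0:
        if renorm_warn:
            log.warning("annualized off-diagonal mass %.4f > 1; renormalizing",
                        sum(p1.values()))
        total = sum(p1.values())
        p1 = {k: v / total for k, v in p1.items()}
        stay = 0.0
    return p1, stay


# ---------------------------------------------------------------------------
# calendar trends and scenarios

@dataclass(frozen=True)
class ScenarioSpec:
    """Counterfactual scenario for CVD incidence after the reference year.

    PLATEAU holds age-specific CVD incidence at its reference-year (2011)
    level; FALL continues the fitted 1991-2011 proportional decline. Both
    scenarios share the historical trend before the reference year and the
    secular decline in cognitive-impairment incidence.
    """

    id: str                         # "PLATEAU" or "FALL"
    reference_year: int = REFERENCE_YEAR
    cvd_trend: float = -0.04        # annual proportional change in CVD incidence
    ci_trend: float = CI_ANNUAL_DECLINE

    def __post_init__(self):
        if self.id not in ("PLATEAU", "FALL"):
            raise ValueError(f"unknown scenario id {self.id!r}")


def fit_cvd_trend(historical: pd.DataFrame, first_year: int = 1991,
                  last_year: int = REFERENCE_YEAR) -> float:
    """Fit the annual proportional change in CVD mortality from a historical
    rate series (columns cause, year, rate), pooling age bands and sexes by
    log-linear regression of log rate on year. The CVD-fall scenario applies
    this slope to CVD incidence (incidence mirroring mortality trends)."""
    sub = historical[(historical["cause"] == "CVD")
                     & historical["year"].between(first_year, last_year)]
    if sub.empty:
        raise ValueError("no historical CVD rates in the trend window")
    if (sub["rate"] <= 0).any():
        raise ValueError("non-positive historical rates")
    X = sm.add_constant(sub["year"].astype(float))
    slope = sm.OLS(np.log(sub["rate"].to_numpy()), X).fit().params.iloc[1]
    return float(np.expm1(slope))


def apply_calendar_trend(p, kind: TransitionKind, year: int,
                         spec: ScenarioSpec) -> np.ndarray:
    """Scale an annual incidence probability by the scenario calendar effect,
    clamped to [0, 1]. FI onset/recovery carry no calendar trend."""
    p = np.asarray(p, dtype=float)
    ref = spec.reference_year
    if kind == TransitionKind.CI_ONSET:
        factor = (1.0 - spec.ci_trend) ** (year - ref)
    elif kind == TransitionKind.CVD_ONSET:
        eff_year = min(year, ref) if spec.id == "PLATEAU" else year
        factor = (1.0 + spec.cvd_trend) ** (eff_year - ref)
    else:
        factor = 1.0
    out = np.clip(p * factor, 0.0, 1.0)
    if np.any(p * factor > 1.0):
        log.warning("calendar trend pushed probability above 1; clamped")
    return out


# ---------------------------------------------------------------------------
# table assembly

@dataclass
class TransitionTable:
    """Annual transition probabilities P[year, sex, age, from, to].

    Axis order: (year, sex in ("F","M"), age 35..100, from-state, to-state).
    Rows over the to-state axis sum to 1; death states are absorbing.
    """

    scenario: str
    years: list[int]
    probs: np.ndarray  # shape (n_years, 2, n_ages, N_STATES, N_STATES)

    def __post_init__(self):
        expected = (len(self.years), 2, AGE_MAX - AGE_MIN + 1, N_STATES, N_STATES)
        if self.probs.shape != expected:
            raise AssemblyError(f"probs shape {self.probs.shape} != {expected}")

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise AssemblyError(f"year {year} not covered by table "
                                f"({self.years[0]}-{self.years[-1]})") from None

    def matrix(self, year: int, sex: str, age: int) -> np.ndarray:
        return self.probs[self.year_index(year), SEXES.index(sex), age - AGE_MIN]

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.probs < -atol):
            raise AssemblyError("negative transition probabilities")
        sums = self.probs.sum(axis=-1)
        bad = np.abs(sums - 1.0) > atol
        if bad.any():
            iy, isx, ia, ifrom = map(lambda a: a[0], np.nonzero(bad))
            raise AssemblyError(
                f"row sums != 1 at {int(bad.sum())} cells; first offender "
                f"year={self.years[iy]} sex={SEXES[isx]} age={ia + AGE_MIN} "
                f"from={HealthState(ifrom).name} (sum={sums[iy, isx, ia, ifrom]:.12f})")
        for d in DEATH_STATES:
            eye = np.zeros(N_STATES)
            eye[int(d)] = 1.0
            if not np.allclose(self.probs[:, :, :, int(d), :], eye, atol=atol):
                raise AssemblyError(f"death state {d.name} is not absorbing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (scenario, year, sex, age, from_state, to_state, probability),
        zero entries omitted."""
        iy, isx, ia, ifr, ito = np.nonzero(self.probs)
        return pd.DataFrame({
            "scenario": self.scenario,
            "year": np.asarray(self.years)[iy],
            "sex": np.array(SEXES)[isx],
            "age": ia + AGE_MIN,
            "from_state": [HealthState(i).name for i in ifr],
            "to_state": [HealthState(i).name for i in ito],
            "probability": self.probs[iy, isx, ia, ifr, ito],
        })


def build_transition_table(logits: dict[TransitionKind, TransitionLogit],
                           mortality,  # StateMortalityTable (mortality module)
                           spec: ScenarioSpec,
                           years) -> TransitionTable:
    """Assemble the annual TransitionTable for one scenario.

    For every (from-state, age, sex, year): annualize the fitted two-year
    incidence probabilities, apply the scenario calendar trend, insert the
    calibrated per-state death probabilities, and condition living movement
    on survival so each row sums to exactly 1.
    """
    missing = [k.value for k in TransitionKind if k not in logits]
    if missing:
        raise AssemblyError(f"missing transition logits: {missing}")

    years = list(years)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_ages = ages.size
    P = np.zeros((len(years), 2, n_ages, N_STATES, N_STATES))

    for d in DEATH_STATES:
        P[:, :, :, int(d), int(d)] = 1.0

    for yi, year in enumerate(years):
        for si, sex in enumerate(SEXES):
            male = 1 if sex == "M" else 0
            # annual incident probabilities by kind and from-state, with trend
            p1_by_state: dict[HealthState, dict[HealthState, np.ndarray]] = {}
            for s in LIVING_STATES:
                p1 = {}
                for kind, target in PERMITTED[s].items():
                    p2 = logits[kind].prob2_ages(ages, male, s)
                    pa = annualize(p2)
                    pa = apply_calendar_trend(pa, kind, year, spec)
                    p1[target] = pa
                p1_by_state[s] = p1

            for s in LIVING_STATES:
                qc = mortality.q(cause="CVD", state=s, sex=sex, year=year)
                qn = mortality.q(cause="NONCVD", state=s, sex=sex, year=year)
                tot = qc + qn
                if np.any(tot > 1.0):  # cause shares preserved, total capped
                    log.warning("total death probability exceeds 1 for %s; "
                                "rescaling causes proportionally", s.name)
                    shrink = np.where(tot > 1.0, 1.0 / tot, 1.0)
                    qc, qn = qc * shrink, qn * shrink
                surv = 1.0 - (qc + qn)
                moves = p1_by_state[s]
                off = sum(moves.values()) if moves else np.zeros(n_ages)
                over = off > 1.0
                if np.any(over):
                    log.warning("off-diagonal mass exceeds 1 for %s; renormalizing",
                                s.name)
                scale = np.where(over, off, 1.0)
                stay = (1.0 - sum(m / scale for m in moves.values())
                        if moves else np.ones(n_ages))
                P[yi, si, :, int(s), int(HealthState.DEATH_CVD)] += qc
                P[yi, si, :, int(s), int(HealthState.DEATH_NONCVD)] += qn
                for target, m in moves.items():
                    P[yi, si, :, int(s), int(target)] += surv * (m / scale)
                P[yi, si, :, int(s), int(s)] += surv * stay

    table = TransitionTable(spec.id, years, P)
    table.validate(atol=1e-9)
    return table
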