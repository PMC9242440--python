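"""Annual cost models per (category, health state, age, sex) cell.

Hospital costs: OLS on the consenting (record-linked) subsample, predictions
imputed to non-consenters. Prescribing: medication lists matched to a
formulary of annual net ingredient costs, then a two-part model. Formal
social care (home care, cleaner): two-part probit + OLS on weekly hours times
a unit cost; daycare and residential care: participation probit times a flat
annual cost. Informal care: two-part hours valued at an opportunity-cost
wage. Healthcare categories can be calibrated multiplicatively to external
totals by age band; all amounts are expressed in 2019 prices via a GDP
deflator series. Predictions are evaluated once on the (state, age, sex)
grid and stored as lookup tables; the projection engine never refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .states import AGE_MAX, AGE_MIN, LIVING_STATES, SEXES, HealthState
from .synthetic import AGE_CENTER, FORMULARY, UnitCosts

log = logging.getLogger(__name__)

PRICE_YEAR = 2019
WEEKS_PER_YEAR = 52

#: cost categories and their reporting groups
HEALTHCARE = ("hospital", "prescribing")
SOCIAL = ("homecare", "cleaner", "daycare", "residential")
INFORMAL = ("informal",)
CATEGORIES = HEALTHCARE + SOCIAL + INFORMAL
GROUPS = {"healthcare": HEALTHCARE, "social": SOCIAL, "informal": INFORMAL}

#: age bands used for external calibration
CALIBRATION_BANDS = ((35, 49), (50, 64), (65, 79), (80, 100))


class CostEstimationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


class DeflatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# deflation

def deflate(amount, from_price_year: int, deflators: pd.DataFrame,
            to_price_year: int = PRICE_YEAR):
    """Re-express an amount in ``to_price_year`` prices:
    amount x index(to) / index(from)."""
    idx = deflators.set_index("year")["index"]
    for y in (from_price_year, to_price_year):
        if y not in idx.index:
            raise DeflatorError(f"deflator series does not cover year {y}")
    return np.asarray(amount, dtype=float) * float(idx[to_price_year]) / float(idx[from_price_year])


# ---------------------------------------------------------------------------
# design helper

def _design(age, male, state, quadratic: bool = True) -> pd.DataFrame:
    age_c = np.atleast_1d(np.asarray(age, float)) - AGE_CENTER
    if isinstance(state, HealthState):
        cvd = np.full(age_c.shape, float(state.has_cvd))
        ci = np.full(age_c.shape, float(state.has_ci))
        fi = np.full(age_c.shape, float(state.has_fi))
    else:
        state = np.asarray(state)
        cvd = np.isin(state, [int(s) for s in HealthState if s.has_cvd]).astype(float)
        ci = np.isin(state, [int(s) for s in HealthState if s.has_ci]).astype(float)
        fi = np.isin(state, [int(s) for s in HealthState if s.has_fi]).astype(float)
    cols = {"const": np.ones_like(age_c), "age_c": age_c}
    if quadratic:
        cols["age_c2"] = age_c ** 2
    cols.update({"male": np.asarray(male, float) * np.ones_like(age_c),
                 "has_cvd": cvd, "has_ci": ci, "has_fi": fi})
    return pd.DataFrame(cols)


def _alive(panel: pd.DataFrame) -> pd.DataFrame:
    dead = [int(HealthState.DEATH_CVD), int(HealthState.DEATH_NONCVD)]
    return panel[~panel["state"].isin(dead)]


# ---------------------------------------------------------------------------
# hospital costs

@dataclass
class HospitalCostModel:
    """OLS of annual hospital cost on state, age (linear + quadratic) and sex,
    fitted on the consenting subsample; predictions impute non-consenters."""

    params: pd.Series
    vcov: pd.DataFrame
    consent_share: float

    def predict(self, age, male, state) -> np.ndarray:
        X = _design(age, male, state)[self.params.index]
        return np.maximum(X.to_numpy() @ self.params.to_numpy(), 0.0)

    def impute(self, panel: pd.DataFrame) -> pd.Series:
        """Observed costs for consenters, model predictions for the rest."""
        pred = self.predict(panel["age"], panel["male"], panel["state"])
        obs = panel["hospital_cost"].to_numpy(dtype=float)
        return pd.Series(np.where(np.isfinite(obs), obs, pred), index=panel.index)


def fit_hospital_costs(panel: pd.DataFrame,
                       consent_floor: float = 0.5) -> HospitalCostModel:
    """Fit the hospital-cost OLS on consenters (rows carrying a cost)."""
    alive = _alive(panel)
    consented = alive[alive["hospital_cost"].notna()]
    if consented.empty:
        raise CostEstimationError("no consented hospital-cost observations")
    share = len(consented) / len(alive)
    if share < consent_floor:
        log.warning("consent share %.2f below floor %.2f", share, consent_floor)
    X = _design(consented["age"], consented["male"], consented["state"])
    X = X[["const"] + [c for c in X.columns[1:] if X[c].nunique() > 1]]
    y = consented["hospital_cost"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CostEstimationError("rank-deficient hospital-cost design")
    res = sm.OLS(y, X).fit(cov_type="HC1")  # robust to skewed cost noise
    return HospitalCostModel(pd.Series(res.params, index=X.columns),
                             pd.DataFrame(res.cov_params(), index=X.columns,
                                          columns=X.columns),
                             consent_share=share)


# ---------------------------------------------------------------------------
# two-part models

@dataclass
class TwoPartModel:
    """Probit participation x conditional-amount OLS (amount per week)."""

    name: str
    probit_params: pd.Series
    ols_params: pd.Series | None   # None for flat-rate (probit-only) models

    def participation(self, age, male, state) -> np.ndarray:
        X = _design(age, male, state, quadratic=False)[self.probit_params.index]
        return norm.cdf(X.to_numpy() @ self.probit_params.to_numpy())

    def conditional_amount(self, age, male, state) -> np.ndarray:
        if self.ols_params is None:
            raise CostEstimationError(f"{self.name}: probit-only model has no amount part")
        X = _design(age, male, state, quadratic=False)[self.ols_params.index]
        amt = X.to_numpy() @ self.ols_params.to_numpy()
        if np.any(amt < 0):
            log.warning("%s: negative conditional amount clamped to 0", self.name)
        return np.maximum(amt, 0.0)


def fit_two_part(panel: pd.DataFrame, column: str, name: str) -> TwoPartModel:
    """Fit participation probit (any use) and conditional OLS (amount among
    users) for a weekly resource-use column."""
    alive = _alive(panel)
    y_any = (alive[column].to_numpy(dtype=float) > 0).astype(int)
    if y_any.sum() == 0 or y_any.sum() == len(y_any):
        raise CostEstimationError(f"{name}: participation outcome degenerate")
    X = _design(alive["age"], alive["male"], alive["state"], quadratic=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probit = sm.Probit(y_any, X).fit(disp=0, maxiter=200)
    users = alive[alive[column] > 0]
    Xu = _design(users["age"], users["male"], users["state"], quadratic=False)
    ols = sm.OLS(users[column].to_numpy(dtype=float), Xu).fit()
    return TwoPartModel(name, pd.Series(probit.params, index=X.columns),
                        pd.Series(ols.params, index=X.columns))


def fit_participation(panel: pd.DataFrame, column: str, name: str) -> TwoPartModel:
    """Probit-only model for flat-rate resources (daycare, residential)."""
    alive = _alive(panel)
    y = (alive[column].to_numpy(dtype=float) > 0).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise CostEstimationError(f"{name}: participation outcome degenerate")
    X = _design(alive["age"], alive["male"], alive["state"], quadratic=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probit = sm.Probit(y, X).fit(disp=0, maxiter=200)
    return TwoPartModel(name, pd.Series(probit.params, index=X.columns), None)


def expected_two_part_cost(model: TwoPartModel, age, male, state,
                           unit_cost: float,
                           weeks: int = WEEKS_PER_YEAR) -> np.ndarray:
    """Expected annual cost: P(any use) x E[amount | use] x unit cost x weeks."""
    return (model.participation(age, male, state)
            * model.conditional_amount(age, male, state) * unit_cost * weeks)


def expected_flat_rate_cost(model: TwoPartModel, age, male, state,
                            annual_cost: float) -> np.ndarray:
    """Expected annual cost for flat-rate resources: P(use) x annual cost."""
    return model.participation(age, male, state) * annual_cost


# ---------------------------------------------------------------------------
# prescribing

_warned_codes: set[str] = set()


def cost_prescribing(med_list, formulary: dict[str, float] | None = None,
                     default_cost: float = 0.0) -> float:
    """Annual prescribing cost: sum of matched annual net ingredient costs.

    Unknown codes contribute ``default_cost`` and are logged once per code.
    """
    formulary = FORMULARY if formulary is None else formulary
    if not formulary:
        raise CostEstimationError("empty formulary table")
    total = 0.0
    for code in med_list:
        if code in formulary:
            total += formulary[code]
        else:
            if code not in _warned_codes:
                log.warning("unknown formulary code %r; using default %.2f",
                            code, default_cost)
                _warned_codes.add(code)
            total += default_cost
    return total


def prescribing_column(panel: pd.DataFrame,
                       formulary: dict[str, float] | None = None) -> pd.Series:
    """Per-record annual prescribing cost, as weekly-equivalent units so the
    shared two-part machinery (which annualizes by x52) applies."""
    costs = panel["med_list"].map(lambda ml: cost_prescribing(ml, formulary))
    return costs / WEEKS_PER_YEAR


# ---------------------------------------------------------------------------
# calibration to external totals

def calibrate_totals(modelled: pd.DataFrame, external: pd.DataFrame) -> pd.Series:
    """Per-age-band multiplicative factors external/modelled.

    Both frames have columns (band, total); bands must match. Applying the
    factors to the modelled cells reproduces the external band totals.
    """
    m = modelled.set_index("band")["total"]
    e = external.set_index("band")["total"]
    if set(m.index) != set(e.index):
        raise CalibrationError(f"band mismatch: {sorted(m.index)} vs {sorted(e.index)}")
    if (e <= 0).any():
        raise CalibrationError("external totals must be positive")
    zero = m[m == 0].index[e[m[m == 0].index] > 0] if (m == 0).any() else []
    if len(zero):
        raise CalibrationError(f"modelled total is zero in bands {list(zero)} "
                               "with positive external totals")
    return (e / m).reindex(m.index)


def band_of(age) -> np.ndarray:
    """Map ages to calibration band labels."""
    age = np.asarray(age)
    out = np.empty(age.shape, dtype=object)
    for lo, hi in CALIBRATION_BANDS:
        out[(age >= lo) & (age <= hi)] = f"{lo}-{hi}"
    return out


# ---------------------------------------------------------------------------
# the assembled lookup table

@dataclass
class CostParameters:
    """Expected annual cost (GBP, 2019 prices) per (category, state, sex, age)."""

    c: np.ndarray  # shape (n_categories, n_living, 2 sexes, n_ages)
    price_year: int = PRICE_YEAR
    categories: tuple[str, ...] = CATEGORIES
    calibration_factors: pd.Series | None = None

    def cost(self, category: str, state: HealthState, sex: str) -> np.ndarray:
        """Annual cost over ages 35..100 for one (category, state, sex)."""
        return self.c[self.categories.index(category), int(state),
                      SEXES.index(sex)]

    def group_cost(self, group: str, state: HealthState, sex: str) -> np.ndarray:
        return sum(self.cost(cat, state, sex) for cat in GROUPS[group])

    def scaled(self, multipliers: dict[str, float]) -> "CostParameters":
        """New table with per-category multipliers applied (PSA draws)."""
        c = self.c.copy()
        for cat, m in multipliers.items():
            c[self.categories.index(cat)] *= m
        return CostParameters(c, self.price_year, self.categories,
                              self.calibration_factors)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        for k, cat in enumerate(self.categories):
            for s in LIVING_STATES:
                for si, sex in enumerate(SEXES):
                    recs.append(pd.DataFrame({
                        "category": cat, "state": s.name, "sex": sex,
                        "age": ages, "annual_cost_gbp_2019": self.c[k, int(s), si]}))
        return pd.concat(recs, ignore_index=True)


@dataclass
class FittedCostModels:
    """The estimation-side bundle the grid is built from."""

    hospital: HospitalCostModel
    prescribing: TwoPartModel
    homecare: TwoPartModel
    cleaner: TwoPartModel
    informal: TwoPartModel
    daycare: TwoPartModel
    residential: TwoPartModel
    unit_costs: UnitCosts = field(default_factory=UnitCosts)


def fit_cost_models(panel: pd.DataFrame,
                    formulary: dict[str, float] | None = None,
                    unit_costs: UnitCosts | None = None) -> FittedCostModels:
    """Fit every cost component on the panel."""
    panel = panel.copy()
    panel["rx_weekly"] = prescribing_column(panel, formulary)
    return FittedCostModels(
        hospital=fit_hospital_costs(panel),
        prescribing=fit_two_part(panel, "rx_weekly", "prescribing"),
        homecare=fit_two_part(panel, "homecare_hours", "homecare"),
        cleaner=fit_two_part(panel, "cleaner_hours", "cleaner"),
        informal=fit_two_part(panel, "informal_hours", "informal"),
        daycare=fit_participation(panel, "daycare_use", "daycare"),
        residential=fit_participation(panel, "in_institution", "residential"),
        unit_costs=unit_costs or UnitCosts(),
    )


def build_cost_parameters(models: FittedCostModels,
                          deflators: pd.DataFrame,
                          external_healthcare_totals: pd.DataFrame | None = None,
                          population: pd.DataFrame | None = None,
                          occupancy: np.ndarray | None = None) -> CostParameters:
    """Evaluate the fitted models on the (category, state, sex, age) grid,
    deflate everything to 2019 prices, and (optionally) calibrate the
    healthcare categories to external totals by age band.

    Calibration needs ``population`` (sex, age, count) and ``occupancy``
    (n_ages, 2, n_living) to weight modelled cell costs into band totals.
    """
    uc = models.unit_costs
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_ages = ages.size
    c = np.zeros((len(CATEGORIES), len(LIVING_STATES), 2, n_ages))
    for s in LIVING_STATES:
        for si, _sex in enumerate(SEXES):
            male = si  # SEXES = ("F", "M")
            c[CATEGORIES.index("hospital"), int(s), si] = models.hospital.predict(
                ages, male, s)
            c[CATEGORIES.index("prescribing"), int(s), si] = expected_two_part_cost(
                models.prescribing, ages, male, s, unit_cost=1.0)
            c[CATEGORIES.index("homecare"), int(s), si] = deflate(
                expected_two_part_cost(models.homecare, ages, male, s,
                                       uc.homecare_per_hour),
                uc.homecare_price_year, deflators)
            c[CATEGORIES.index("cleaner"), int(s), si] = expected_two_part_cost(
                models.cleaner, ages, male, s, uc.cleaner_per_hour)
            c[CATEGORIES.index("informal"), int(s), si] = expected_two_part_cost(
                models.informal, ages, male, s, uc.informal_per_hour)
            c[CATEGORIES.index("daycare"), int(s), si] = deflate(
                expected_flat_rate_cost(models.daycare, ages, male, s,
                                        uc.daycare_per_year),
                uc.daycare_price_year, deflators)
            c[CATEGORIES.index("residential"), int(s), si] = deflate(
                expected_flat_rate_cost(models.residential, ages, male, s,
                                        uc.residential_per_year),
                uc.residential_price_year, deflators)

    factors = None
    if external_healthcare_totals is not None:
        if population is None or occupancy is None:
            raise CalibrationError(
                "calibration needs population and occupancy weights")
        hc = sum(c[CATEGORIES.index(cat)] for cat in HEALTHCARE)  # (nliv,2,nages)
        pop = population.pivot_table(index="age", columns="sex",
                                     values="count").reindex(ages)
        w = np.stack([pop["F"].to_numpy(), pop["M"].to_numpy()], axis=0)  # (2, ages)
        occ = np.moveaxis(occupancy, 0, -1)  # (2, nliv, ages)
        cell_counts = occ * w[:, None, :]
        modelled_age = (np.moveaxis(hc, 0, 1) * cell_counts).sum(axis=(0, 1))
        bands = band_of(ages)
        modelled = pd.DataFrame({"band": bands, "total": modelled_age}) \
            .groupby("band", as_index=False).sum()
        factors = calibrate_totals(modelled, external_healthcare_totals)
        per_age = pd.Series(bands).map(factors).to_numpy(dtype=float)
        for cat in HEALTHCARE:
            c[CATEGORIES.index(cat)] *= per_age[None, None, :]
    return CostParameters(c, calibration_factors=factors)
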