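"""Open-cohort annual Markov projection with economic accounting.

The population is propagated as expected cohort counts by single year of age
(35-100), sex and health state. Each year every cohort transitions per the
scenario table, survivors age one year (age 100 is terminal: survivors stay
100 until death), a new disease-free cohort of 35-year-olds enters, and
deaths accumulate in the absorbing cause-of-death states. Costs and QALYs
are attached per year from the (state, age, sex) lookup tables, discounted
from the outcome-window base year, and accumulated over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import CostParameters, GROUPS
from .states import (
    AGE_MAX,
    AGE_MIN,
    DEATH_STATES,
    LIVING_STATES,
    N_STATES,
    SEXES,
    HealthState,
)
from .transitions import TransitionTable
from .utility import UtilityParameters, utility_grid

N_AGES = AGE_MAX - AGE_MIN + 1

LIVING_IDX = np.array([int(s) for s in LIVING_STATES])
CVD_LIVING_IDX = np.array([int(s) for s in LIVING_STATES if s.has_cvd])


class ProjectionError(RuntimeError):
    pass


@dataclass
class StateDistribution:
    """Population counts by year, state, sex and single year of age.

    ``counts`` has shape (n_years, N_STATES, 2 sexes, n_ages). Death-state
    counts are cumulative and recorded at age at death.
    """

    years: list[int]
    counts: np.ndarray
    entrants_added: np.ndarray | None = None  # (n_years,) persons entering at 35

    def at(self, year: int) -> np.ndarray:
        return self.counts[self.years.index(year)]

    def living(self, year: int) -> np.ndarray:
        """Living-state counts (n_living, 2, n_ages) for one year."""
        return self.at(year)[LIVING_IDX]

    def total_living(self, year: int) -> float:
        return float(self.living(year).sum())

    def to_frame(self) -> pd.DataFrame:
        iy, ist, isx, ia = np.nonzero(self.counts)
        return pd.DataFrame({
            "year": np.asarray(self.years)[iy],
            "state": [HealthState(i).name for i in ist],
            "sex": np.array(SEXES)[isx],
            "age": ia + AGE_MIN,
            "count": self.counts[iy, ist, isx, ia],
        })


def distribution_from_frame(df: pd.DataFrame, year: int) -> np.ndarray:
    """(N_STATES, 2, n_ages) counts from a long (sex, age, state, count) frame."""
    out = np.zeros((N_STATES, 2, N_AGES))
    for _, r in df.iterrows():
        out[int(HealthState[r["state"]]), SEXES.index(r["sex"]),
            int(r["age"]) - AGE_MIN] += r["count"]
    return out


def advance_year(counts: np.ndarray, table: TransitionTable, year: int,
                 entrants: dict[str, float] | None = None) -> np.ndarray:
    """One annual cycle: transition at current age, then age survivors +1
    (100 is terminal), then insert 35-year-old disease-free entrants.

    ``counts``: (N_STATES, 2, n_ages) at the start of ``year``; returns the
    start-of-next-year array. Deaths stay at their age at death.
    """
    if np.any(counts < 0):
        raise ProjectionError("negative input counts")
    P = table.probs[table.year_index(year)]          # (2, ages, from, to)
    # flows[to, sex, age] = sum_from counts[from, sex, age] * P[sex, age, from, to]
    flows = np.einsum("fsa,saft->tsa", counts, P)

    new = np.zeros_like(counts)
    for d in DEATH_STATES:
        new[int(d)] = flows[int(d)]                  # cumulative, no ageing
    living_flows = flows[LIVING_IDX]
    new[LIVING_IDX, :, 1:] = living_flows[:, :, :-1]
    new[LIVING_IDX, :, -1] += living_flows[:, :, -1]  # age-100 pile-up

    if entrants:
        for sex, n in entrants.items():
            if n < 0:
                raise ProjectionError("negative entrants")
            new[int(HealthState.FREE), SEXES.index(sex), 0] += n

    inn, out = counts.sum(), new.sum() - sum((entrants or {}).values())
    if abs(inn - out) > 1e-6 * max(inn, 1.0):
        raise ProjectionError(f"conservation violated: {inn} -> {out}")
    return new


def project(initial: np.ndarray, entrants: pd.DataFrame | None,
            table: TransitionTable, start_year: int = 2011,
            end_year: int = 2029) -> StateDistribution:
    """Propagate the population from ``start_year`` to ``end_year``.

    ``initial``: (N_STATES, 2, n_ages) counts at the start of ``start_year``;
    ``entrants``: long frame (year, sex, entrants) of new 35-year-olds.
    Deterministic expected-value propagation.
    """
    if start_year < table.years[0]:
        raise ProjectionError(
            f"start year {start_year} precedes table coverage {table.years[0]}")
    ent = {}
    if entrants is not None:
        for _, r in entrants.iterrows():
            ent.setdefault(int(r["year"]), {})[r["sex"]] = float(r["entrants"])

    years = list(range(start_year, end_year + 1))
    counts = np.zeros((len(years), N_STATES, 2, N_AGES))
    counts[0] = initial
    added = np.zeros(len(years))
    for yi, year in enumerate(years[:-1]):
        e = ent.get(year + 1, {})
        counts[yi + 1] = advance_year(counts[yi], table, year, e)
        added[yi + 1] = sum(e.values())
    return StateDistribution(years, counts, added)


# ---------------------------------------------------------------------------
# economics

@dataclass(frozen=True)
class EconConfig:
    """Valuation and discounting choices for the outcome window."""

    qaly_value: float = 60_000.0     # GBP per QALY (sensitivity: 30,000)
    discount_costs: float = 0.0      # 0 or 0.035
    discount_qalys: float = 0.0      # 0, 0.015 or 0.035
    window: tuple[int, int] = (2020, 2029)
    price_year: int = 2019

    def __post_init__(self):
        if self.qaly_value <= 0:
            raise ValueError("qaly_value must be positive")
        if self.discount_costs < 0 or self.discount_qalys < 0:
            raise ValueError("discount rates must be >= 0")


@dataclass
class EconResult:
    """Per-year and cumulative costs (GBP 2019) and QALYs for one scenario."""

    scenario: str
    per_year: pd.DataFrame         # year, per-category, group and qaly columns
    cumulative: pd.Series          # discounted sums over the window
    config: EconConfig
    trajectory: StateDistribution = field(repr=False, default=None)

    def __getitem__(self, key: str) -> float:
        return float(self.cumulative[key])


def attach_economics(trajectory: StateDistribution, costs: CostParameters,
                     utils: UtilityParameters, config: EconConfig,
                     scenario: str = "") -> EconResult:
    """Cost and QALY accounting over the trajectory.

    Per-year totals are count-weighted sums of the (category, state, sex,
    age) cost cells and the utility grid; discounting is applied from the
    first window year; cumulative values sum discounted years inside the
    window.
    """
    ugrid = utility_grid(utils)
    base = config.window[0]
    rows = []
    for year in trajectory.years:
        live = trajectory.living(year)           # (n_living, 2, n_ages)
        row = {"year": year}
        for cat in costs.categories:
            k = costs.categories.index(cat)
            row[cat] = float((live * costs.c[k]).sum())
        for group, cats in GROUPS.items():
            row[group] = sum(row[c] for c in cats)
        row["qalys"] = float((live * ugrid).sum())
        t = year - base
        dfc = (1 + config.discount_costs) ** (-t) if t >= 0 else 1.0
        dfq = (1 + config.discount_qalys) ** (-t) if t >= 0 else 1.0
        for group in GROUPS:
            row[f"{group}_disc"] = row[group] * dfc
        row["qalys_disc"] = row["qalys"] * dfq
        rows.append(row)
    per_year = pd.DataFrame(rows)

    w = per_year["year"].between(*config.window)
    cum = {f"{g}": float(per_year.loc[w, f"{g}_disc"].sum()) for g in GROUPS}
    cum["total_costs"] = sum(cum[g] for g in GROUPS)
    cum["qalys"] = float(per_year.loc[w, "qalys_disc"].sum())
    cum["qaly_value"] = cum["qalys"] * config.qaly_value
    return EconResult(scenario, per_year, pd.Series(cum), config, trajectory)


# ---------------------------------------------------------------------------
# epidemiological summaries

def epi_summaries(trajectory: StateDistribution,
                  table: TransitionTable) -> pd.DataFrame:
    """Annual CVD incidence and mortality per 100,000 and prevalence (%)
    among the living population aged 35-100 at the start of each year."""
    rows = []
    for year in trajectory.years:
        live = trajectory.living(year)
        pop = live.sum()
        if pop <= 0:
            raise ProjectionError(f"zero living population in {year}")
        prev = trajectory.at(year)[CVD_LIVING_IDX].sum() / pop * 100.0

        incidence = np.nan
        cvd_deaths = np.nan
        if year in table.years[:-1] or year in table.years:
            P = table.probs[table.year_index(year)]
            counts = trajectory.at(year)
            new_cvd = 0.0
            deaths = 0.0
            for s in LIVING_STATES:
                mass = counts[int(s)]                      # (2, ages)
                p_s = P[:, :, int(s), :]                   # (2, ages, to)
                if not s.has_cvd:
                    cvd_targets = [int(t) for t in LIVING_STATES if t.has_cvd]
                    new_cvd += (mass * p_s[:, :, cvd_targets].sum(-1)).sum()
                deaths += (mass * p_s[:, :, int(HealthState.DEATH_CVD)]).sum()
            incidence = new_cvd / pop * 100_000.0
            cvd_deaths = deaths / pop * 100_000.0
        rows.append({"year": year, "cvd_incidence_per_100k": incidence,
                     "cvd_prevalence_pct": prev,
                     "cvd_mortality_per_100k": cvd_deaths})
    return pd.DataFrame(rows)
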