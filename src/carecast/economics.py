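"""Scenario comparison, excess-cost attribution and probabilistic
sensitivity analysis.

The net monetary cost of one scenario against another is the difference in
cumulative costs plus the value of QALYs lost (willingness-to-pay per QALY
times the QALY shortfall). Disease-specific excess costs use a counterfactual
state remap — the same people, identical in age, sex and other disabilities,
without the disease (dementia compared against functional impairment only) —
so attribution reflects the disease itself rather than the whole spend of
diseased persons. The PSA draws transition-logit coefficient vectors from
their estimated covariance and independent per-category cost multipliers
from a symmetric beta shaped so the central 95% interval is [0.8, 1.2],
rebuilds the scenario tables, reprojects, and reports empirical percentile
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .costs import CostParameters, GROUPS
from .projection import (
    EconConfig,
    EconResult,
    StateDistribution,
    attach_economics,
    project,
)
from .states import AGE_MIN, DISEASE_REMAPS, LIVING_STATES, HealthState
from .transitions import ScenarioSpec, TransitionLogit, build_transition_table
from .utility import UtilityParameters, utility_grid

#: age bands used in the cost-of-illness tables
REPORT_BANDS = ((35, 64), (65, 79), (80, 100))


class ComparisonError(ValueError):
    pass


class PSAError(RuntimeError):
    pass


@dataclass
class NetMonetaryResult:
    """Componentwise scenario difference (scenario1 - scenario2), GBP."""

    delta_healthcare: float
    delta_social: float
    delta_informal: float
    delta_total_costs: float
    delta_qalys: float
    qaly_value: float

    @property
    def value_of_qalys_lost(self) -> float:
        return self.qaly_value * (-self.delta_qalys)

    @property
    def net_monetary_cost(self) -> float:
        return self.delta_total_costs + self.value_of_qalys_lost

    def as_series(self) -> pd.Series:
        return pd.Series({
            "delta_healthcare": self.delta_healthcare,
            "delta_social": self.delta_social,
            "delta_informal": self.delta_informal,
            "delta_total_costs": self.delta_total_costs,
            "delta_qalys": self.delta_qalys,
            "value_of_qalys_lost": self.value_of_qalys_lost,
            "net_monetary_cost": self.net_monetary_cost,
        })


def compare_scenarios(res1: EconResult, res2: EconResult,
                      qaly_value: float | None = None) -> NetMonetaryResult:
    """Difference res1 - res2 over the shared outcome window."""
    if res1.config != res2.config:
        raise ComparisonError("results were produced under different configs")
    lam = qaly_value if qaly_value is not None else res1.config.qaly_value
    d = res1.cumulative - res2.cumulative
    return NetMonetaryResult(
        delta_healthcare=float(d["healthcare"]),
        delta_social=float(d["social"]),
        delta_informal=float(d["informal"]),
        delta_total_costs=float(d["total_costs"]),
        delta_qalys=float(d["qalys"]),
        qaly_value=lam,
    )


# ---------------------------------------------------------------------------
# excess costs / cost of illness

def _band_mask(ages: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return (ages >= lo) & (ages <= hi)


def excess_costs(trajectory: StateDistribution, costs: CostParameters,
                 utils: UtilityParameters, disease: str, year: int,
                 qaly_value: float = 60_000.0) -> pd.DataFrame:
    """Excess (attributable) costs of a disease in one year, total and per
    affected person-year, by category group and age band.

    Excess = actual cost minus the cost of the same people under the
    counterfactual state remap; the QALY loss is counterfactual minus actual
    utility, valued at ``qaly_value``.
    """
    remap = DISEASE_REMAPS[disease.upper()]
    live = trajectory.living(year)       # (n_living, 2, n_ages)
    ugrid = utility_grid(utils)
    ages = np.arange(live.shape[2]) + AGE_MIN

    affected = np.zeros_like(live)
    for s in remap.affected_states():
        affected[int(s)] = live[int(s)]
    total_affected = affected.sum()
    if total_affected <= 0:
        raise ComparisonError(f"{disease}: zero prevalence in {year}; "
                              "per-person excess undefined")

    rows = []
    bands = list(REPORT_BANDS) + [(35, 100)]
    for lo, hi in bands:
        m = _band_mask(ages, lo, hi)
        row = {"band": f"{lo}-{hi}" if (lo, hi) != (35, 100) else "all",
               "disease": disease.upper()}
        py = affected[:, :, m].sum()
        row["person_years"] = float(py)
        for group in GROUPS:
            ex = 0.0
            for s in remap.affected_states():
                cf = remap.mapping[s]
                k_diff = sum(
                    costs.c[costs.categories.index(cat), int(s)]
                    - costs.c[costs.categories.index(cat), int(cf)]
                    for cat in GROUPS[group])          # (2, n_ages)
                ex += (affected[int(s)][:, m] * k_diff[:, m]).sum()
            row[group] = float(ex)
            row[f"{group}_per_py"] = float(ex / py) if py > 0 else np.nan
        qloss = 0.0
        for s in remap.affected_states():
            cf = remap.mapping[s]
            qloss += (affected[int(s)][:, m]
                      * (ugrid[int(cf)] - ugrid[int(s)])[:, m]).sum()
        row["qalys_lost"] = float(qloss)
        row["qaly_loss_value"] = float(qloss * qaly_value)
        row["qaly_loss_value_per_py"] = float(qloss * qaly_value / py) if py > 0 else np.nan
        row["total_value"] = (row["healthcare"] + row["social"]
                              + row["informal"] + row["qaly_loss_value"])
        rows.append(row)
    return pd.DataFrame(rows)


def cost_of_illness(trajectory: StateDistribution, costs: CostParameters,
                    utils: UtilityParameters, disease: str, year: int,
                    qaly_value: float = 60_000.0) -> pd.DataFrame:
    """Total cost of illness (excess attribution) by age band for one year."""
    df = excess_costs(trajectory, costs, utils, disease, year, qaly_value)
    return df[["disease", "band", "person_years", "healthcare", "social",
               "informal", "qalys_lost", "qaly_loss_value", "total_value"]]


# ---------------------------------------------------------------------------
# PSA

def beta_multiplier_alpha(lo: float = 0.8, hi: float = 1.2) -> float:
    """Shape of the symmetric beta behind the cost multiplier 2*B,
    B ~ Beta(a, a), such that the central 95% interval of 2*B is [lo, hi]."""
    if not np.isclose(lo + hi, 2.0):
        raise PSAError("multiplier interval must be symmetric about 1")
    if np.isclose(hi, lo):
        return float("inf")  # degenerate: multiplier fixed at 1
    target = lo / 2.0  # P(B <= target) = 0.025

    def f(a):
        return beta_dist.ppf(0.025, a, a) - target

    return float(brentq(f, 1.0, 5_000.0, xtol=1e-12))


def sample_cost_multipliers(rng: np.random.Generator, categories,
                            alpha: float, shared: bool = False) -> dict[str, float]:
    """One multiplier per cost category (or one shared draw)."""
    if not np.isfinite(alpha):
        return {c: 1.0 for c in categories}
    if shared:
        m = 2.0 * rng.beta(alpha, alpha)
        return {c: m for c in categories}
    return {c: 2.0 * rng.beta(alpha, alpha) for c in categories}


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 1000
    seed: int = 0
    multiplier_interval: tuple[float, float] = (0.8, 1.2)
    shared_multiplier: bool = False

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")


@dataclass
class PSAResult:
    point: pd.Series                  # deterministic component values
    draws: pd.DataFrame               # one row per draw
    intervals: pd.DataFrame           # component, point, lo95, hi95
    config: PSAConfig = field(repr=False, default=None)


def run_psa(logits: dict, mortality_table, spec1: ScenarioSpec,
            spec2: ScenarioSpec, initial: np.ndarray,
            entrants: pd.DataFrame, cost_params: CostParameters,
            utils: UtilityParameters, econ: EconConfig,
            years, config: PSAConfig,
            start_year: int = 2011, end_year: int = 2029) -> PSAResult:
    """Probabilistic sensitivity analysis of the scenario comparison.

    Each draw samples transition-logit coefficients from their covariance
    and per-category cost multipliers, rebuilds both scenario tables,
    reprojects, and differences the economics. Cost multipliers are shared
    between scenarios within a draw; QALY components carry epidemiological
    uncertainty only. Deterministic given ``config.seed``.
    """
    for kind, lg in logits.items():
        if lg.vcov is not None:
            vals = np.linalg.eigvalsh(lg.vcov.values)
            if vals.min() < -1e-10:
                raise PSAError(f"vcov for {kind} is not positive semi-definite")

    rng = np.random.default_rng(config.seed)
    alpha = beta_multiplier_alpha(*config.multiplier_interval)

    def run_one(lg: dict, mult: dict[str, float]) -> pd.Series:
        cp = cost_params.scaled(mult)
        out = {}
        for spec in (spec1, spec2):
            table = build_transition_table(lg, mortality_table, spec, years)
            traj = project(initial, entrants, table, start_year, end_year)
            out[spec.id] = attach_economics(traj, cp, utils, econ, spec.id)
        nm = compare_scenarios(out[spec1.id], out[spec2.id])
        return nm.as_series()

    point = run_one(logits, {c: 1.0 for c in cost_params.categories})

    records = []
    for _ in range(config.n_draws):
        drawn = {k: lg.perturbed(rng) for k, lg in logits.items()}
        mult = sample_cost_multipliers(rng, cost_params.categories, alpha,
                                       config.shared_multiplier)
        records.append(run_one(drawn, mult))
    draws = pd.DataFrame(records).reset_index(drop=True)

    lo = draws.quantile(0.025)
    hi = draws.quantile(0.975)
    intervals = pd.DataFrame({"component": draws.columns,
                              "point": point[draws.columns].to_numpy(),
                              "lo95": lo.to_numpy(), "hi95": hi.to_numpy(),
                              "n_draws": config.n_draws, "seed": config.seed})
    return PSAResult(point, draws, intervals, config)
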