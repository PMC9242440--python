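"""Model/Results surface tying the pipeline together.

:class:`CareTrajectoryModel` is built from data — a biennial health panel,
an initial population distribution, entrant projections, historical
cause-specific mortality and a deflator series. ``fit()`` estimates every
component (transition logits, state-mortality contrasts, the population
mortality projection, cost and utility lookup tables) and returns a
:class:`CareTrajectoryResults` carrying the estimates; projection, scenario
comparison, excess-cost attribution, PSA and plotting hang off the results
object, statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costs as cc
from . import economics as ce
from . import mortality as cm
from . import projection as cp
from . import synthetic as cs
from . import transitions as ct
from . import utility as cu
from .states import AGE_MIN, LIVING_STATES, SEXES, HealthState


class CareTrajectoryModel:
    """Open-cohort multi-state model of CVD, cognitive/functional impairment
    and dementia with cost and QALY projection.

    Parameters
    ----------
    panel : DataFrame
        Biennial panel (columns as produced by
        :func:`carecast.synthetic.generate_panel`).
    initial_distribution : DataFrame
        Long (year, sex, age, state, count) population at the reference year.
    entrants : DataFrame
        (year, sex, entrants) new 35-year-olds entering disease-free.
    historical_mortality : DataFrame
        (cause, sex, age_band, age_mid, year, rate) historical series.
    deflators : DataFrame
        (year, index) price deflator, 2019 = reference.
    """

    def __init__(self, panel: pd.DataFrame, initial_distribution: pd.DataFrame,
                 entrants: pd.DataFrame, historical_mortality: pd.DataFrame,
                 deflators: pd.DataFrame,
                 unit_costs: cs.UnitCosts | None = None,
                 utility_params: cu.UtilityParameters | None = None,
                 external_healthcare_totals: pd.DataFrame | None = None,
                 formulary: dict[str, float] | None = None,
                 reference_year: int = 2011):
        self.panel = panel
        self.initial_distribution = initial_distribution
        self.entrants = entrants
        self.historical_mortality = historical_mortality
        self.deflators = deflators
        self.unit_costs = unit_costs or cs.UnitCosts()
        self.utility_params = utility_params or cu.UtilityParameters()
        self.external_healthcare_totals = external_healthcare_totals
        self.formulary = formulary
        self.reference_year = reference_year

    @classmethod
    def from_synthetic(cls, seed: int = 0, n_individuals: int = 20_000,
                       truth: cs.GroundTruth | None = None,
                       total_population: float = 33_000_000.0,
                       **kwargs) -> "CareTrajectoryModel":
        """Build the model from the synthetic generator's study conditions."""
        truth = truth or cs.GroundTruth()
        config = cs.PanelConfig(n_individuals=n_individuals, seed=seed,
                                truth=truth)
        panel = cs.generate_panel(config)
        model = cls(
            panel=panel,
            initial_distribution=cs.initial_distribution(
                truth, total_population=total_population),
            entrants=cs.entrant_projections(),
            historical_mortality=cs.historical_mortality(),
            deflators=cs.deflator_series(),
            utility_params=cu.UtilityParameters(
                norms=dict(truth.utility.norms),
                mult_cvd=truth.utility.mult_cvd,
                mult_ci=truth.utility.mult_ci,
                mult_dementia=truth.utility.mult_dementia,
                adl_decrement=truth.utility.adl_decrement,
                adl_means=dict(truth.adl_means)),
            **kwargs)
        model.truth = truth
        return model

    # -- helpers -----------------------------------------------------------

    def _initial_counts(self) -> np.ndarray:
        return cp.distribution_from_frame(self.initial_distribution,
                                          self.reference_year)

    def _occupancy(self) -> np.ndarray:
        """(n_ages, 2, n_living) state shares from the initial distribution."""
        counts = self._initial_counts()
        # counts[liv, sex, age] -> occ[age, sex, liv]
        occ = counts[[int(s) for s in LIVING_STATES]].transpose(2, 1, 0)
        tot = occ.sum(-1, keepdims=True)
        free = np.zeros(len(LIVING_STATES))
        free[int(HealthState.FREE)] = 1.0
        occ = np.where(tot > 0, occ / np.maximum(tot, 1e-300), free)
        return occ

    def fit(self, years=None, horizon: int = 2030) -> "CareTrajectoryResults":
        """Estimate every component and assemble the scenario machinery."""
        years = list(years) if years is not None else list(range(2006, horizon + 1))
        logits = ct.fit_transition_logits(self.panel)
        state_mort = cm.fit_state_mortality(self.panel)
        rates = cm.project_population_mortality(self.historical_mortality,
                                                horizon=horizon)
        occupancy = self._occupancy()
        mort_table = cm.build_state_mortality_table(rates, state_mort,
                                                    occupancy, years=years)
        cvd_trend = ct.fit_cvd_trend(self.historical_mortality,
                                     last_year=self.reference_year)
        cost_models = cc.fit_cost_models(self.panel, self.formulary,
                                         self.unit_costs)
        population = self.initial_distribution.groupby(
            ["sex", "age"], as_index=False)["count"].sum()
        cost_params = cc.build_cost_parameters(
            cost_models, self.deflators,
            external_healthcare_totals=self.external_healthcare_totals,
            population=population, occupancy=occupancy)
        return CareTrajectoryResults(
            model=self, transition_logits=logits, state_mortality=state_mort,
            population_mortality=rates, mortality_table=mort_table,
            cvd_trend=cvd_trend, cost_models=cost_models,
            cost_params=cost_params, utility_params=self.utility_params,
            years=years)


@dataclass
class CareTrajectoryResults:
    """Fitted components plus projection, comparison and PSA methods."""

    model: CareTrajectoryModel
    transition_logits: dict
    state_mortality: cm.StateMortalityModel
    population_mortality: cm.MortalityRates
    mortality_table: cm.StateMortalityTable
    cvd_trend: float
    cost_models: cc.FittedCostModels
    cost_params: cc.CostParameters
    utility_params: cu.UtilityParameters
    years: list[int]
    _tables: dict = field(default_factory=dict, repr=False)

    # -- scenario machinery ------------------------------------------------

    def scenario_spec(self, scenario: str) -> ct.ScenarioSpec:
        return ct.ScenarioSpec(scenario.upper(),
                               reference_year=self.model.reference_year,
                               cvd_trend=self.cvd_trend)

    def transition_table(self, scenario: str) -> ct.TransitionTable:
        key = scenario.upper()
        if key not in self._tables:
            self._tables[key] = ct.build_transition_table(
                self.transition_logits, self.mortality_table,
                self.scenario_spec(key), self.years)
        return self._tables[key]

    def project(self, scenario: str, start_year: int = 2011,
                end_year: int = 2029) -> cp.StateDistribution:
        return cp.project(self.model._initial_counts(), self.model.entrants,
                          self.transition_table(scenario), start_year, end_year)

    def economics(self, scenario: str,
                  econ: cp.EconConfig | None = None) -> cp.EconResult:
        econ = econ or cp.EconConfig()
        traj = self.project(scenario)
        return cp.attach_economics(traj, self.cost_params,
                                   self.utility_params, econ, scenario.upper())

    def compare(self, econ: cp.EconConfig | None = None,
                scenario1: str = "PLATEAU",
                scenario2: str = "FALL") -> ce.NetMonetaryResult:
        econ = econ or cp.EconConfig()
        return ce.compare_scenarios(self.economics(scenario1, econ),
                                    self.economics(scenario2, econ))

    def epi_summaries(self, scenario: str) -> pd.DataFrame:
        return cp.epi_summaries(self.project(scenario),
                                self.transition_table(scenario))

    def excess_costs(self, disease: str, year: int = 2020,
                     scenario: str = "FALL",
                     qaly_value: float = 60_000.0) -> pd.DataFrame:
        return ce.excess_costs(self.project(scenario), self.cost_params,
                               self.utility_params, disease, year, qaly_value)

    def cost_of_illness(self, disease: str, year: int = 2020,
                        scenario: str = "FALL",
                        qaly_value: float = 60_000.0) -> pd.DataFrame:
        return ce.cost_of_illness(self.project(scenario), self.cost_params,
                                  self.utility_params, disease, year, qaly_value)

    def run_psa(self, psa: ce.PSAConfig | None = None,
                econ: cp.EconConfig | None = None) -> ce.PSAResult:
        psa = psa or ce.PSAConfig()
        econ = econ or cp.EconConfig()
        return ce.run_psa(self.transition_logits, self.mortality_table,
                          self.scenario_spec("PLATEAU"),
                          self.scenario_spec("FALL"),
                          self.model._initial_counts(), self.model.entrants,
                          self.cost_params, self.utility_params, econ,
                          self.years, psa)

    # -- reporting ---------------------------------------------------------

    def summary(self, econ: cp.EconConfig | None = None) -> str:
        """Plain-text summary of the scenario comparison."""
        econ = econ or cp.EconConfig()
        nm = self.compare(econ)
        epi1 = self.epi_summaries("PLATEAU")
        epi2 = self.epi_summaries("FALL")
        last = epi1["year"].max()
        e1 = epi1[epi1["year"] == last].iloc[0]
        e2 = epi2[epi2["year"] == last].iloc[0]
        lines = [
            "Care-trajectory scenario comparison (PLATEAU - FALL)",
            "=" * 56,
            f"Outcome window          {econ.window[0]}-{econ.window[1]}  "
            f"(GBP {econ.price_year} prices)",
            f"QALY value              GBP {econ.qaly_value:,.0f}",
            f"Discounting             costs {econ.discount_costs:.1%}, "
            f"QALYs {econ.discount_qalys:.1%}",
            f"Fitted CVD trend (FALL) {self.cvd_trend:+.3%}/yr",
            "-" * 56,
            f"D healthcare costs      GBP {nm.delta_healthcare / 1e9:10.2f} bn",
            f"D social care costs     GBP {nm.delta_social / 1e9:10.2f} bn",
            f"D informal care value   GBP {nm.delta_informal / 1e9:10.2f} bn",
            f"D total costs           GBP {nm.delta_total_costs / 1e9:10.2f} bn",
            f"D QALYs                     {nm.delta_qalys:10,.0f}",
            f"Value of QALYs lost     GBP {nm.value_of_qalys_lost / 1e9:10.2f} bn",
            f"Net monetary cost       GBP {nm.net_monetary_cost / 1e9:10.2f} bn",
            "-" * 56,
            f"CVD incidence {last}: PLATEAU "
            f"{e1['cvd_incidence_per_100k']:.0f} vs FALL "
            f"{e2['cvd_incidence_per_100k']:.0f} per 100,000",
            f"CVD prevalence {last}: PLATEAU {e1['cvd_prevalence_pct']:.1f}% "
            f"vs FALL {e2['cvd_prevalence_pct']:.1f}%",
        ]
        return "\n".join(lines)

    def plot_epidemiology(self, ax=None):
        """Fig-style incidence/prevalence trajectories for both scenarios."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(10, 4))
        for scen, style in (("PLATEAU", "-"), ("FALL", "--")):
            epi = self.epi_summaries(scen)
            ax[0].plot(epi["year"], epi["cvd_incidence_per_100k"], style,
                       label=scen)
            ax[1].plot(epi["year"], epi["cvd_prevalence_pct"], style,
                       label=scen)
        ax[0].set_ylabel("CVD incidence per 100,000 (35-100)")
        ax[1].set_ylabel("CVD prevalence (%)")
        for a in ax:
            a.set_xlabel("year")
            a.legend()
        return ax
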