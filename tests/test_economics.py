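"""Scenario comparison, excess-cost attribution and the PSA."""

import numpy as np
import pandas as pd
import pytest

from carecast.costs import CATEGORIES, CostParameters
from carecast.economics import (
    ComparisonError,
    NetMonetaryResult,
    PSAConfig,
    beta_multiplier_alpha,
    compare_scenarios,
    cost_of_illness,
    excess_costs,
    sample_cost_multipliers,
)
from carecast.projection import EconConfig, N_AGES, project
from carecast.states import AGE_MIN, LIVING_STATES, N_STATES, HealthState
from carecast.utility import UtilityParameters

from test_projection import identity_table, seed_counts, _flat_utility


def _econ_result(values, config=None):
    from carecast.projection import EconResult

    config = config or EconConfig()
    cum = {"healthcare": 0.0, "social": 0.0, "informal": 0.0, "qalys": 0.0}
    cum.update(values)
    cum["total_costs"] = cum["healthcare"] + cum["social"] + cum["informal"]
    cum["qaly_value"] = cum["qalys"] * config.qaly_value
    return EconResult("X", pd.DataFrame(), pd.Series(cum), config)


def test_identical_results_give_zero_difference():
    r = _econ_result({"healthcare": 5e9, "qalys": 1e6})
    nm = compare_scenarios(r, r)
    assert nm.net_monetary_cost == 0.0
    assert all(v == 0.0 for v in nm.as_series())


def test_net_monetary_identity_example():
    """Cost difference 21.6bn plus 32.3bn of QALY losses -> 53.9bn."""
    r1 = _econ_result({"healthcare": 21.6e9, "qalys": 0.0})
    r2 = _econ_result({"healthcare": 0.0, "qalys": 32.3e9 / 60_000.0})
    nm = compare_scenarios(r1, r2)
    assert nm.delta_total_costs == pytest.approx(21.6e9)
    assert nm.value_of_qalys_lost == pytest.approx(32.3e9)
    assert nm.net_monetary_cost == pytest.approx(53.9e9)


def test_half_qaly_value_halves_qaly_component():
    r1 = _econ_result({"qalys": -540_000.0})
    r2 = _econ_result({"qalys": 0.0})
    nm60 = compare_scenarios(r1, r2, qaly_value=60_000.0)
    nm30 = compare_scenarios(r1, r2, qaly_value=30_000.0)
    assert nm30.value_of_qalys_lost == pytest.approx(
        nm60.value_of_qalys_lost / 2)
    assert nm30.delta_total_costs == nm60.delta_total_costs


def test_mismatched_configs_rejected():
    r1 = _econ_result({}, EconConfig(qaly_value=60_000.0))
    r2 = _econ_result({}, EconConfig(qaly_value=30_000.0))
    with pytest.raises(ComparisonError):
        compare_scenarios(r1, r2)


def test_net_monetary_identity_randomized(rng):
    """net = Dcosts + lambda x QALY-loss holds exactly, 1,000 random draws."""
    for _ in range(1000):
        vals = rng.normal(0, 1e9, 5)
        nm = NetMonetaryResult(*vals[:3], delta_total_costs=vals[:3].sum(),
                               delta_qalys=vals[4] / 1e4,
                               qaly_value=60_000.0)
        lhs = nm.net_monetary_cost
        rhs = nm.delta_total_costs + 60_000.0 * (-nm.delta_qalys)
        assert lhs == rhs  # identity, not approximation


# ---------------------------------------------------------------------------
# excess costs

def _cost_params_by_state(per_state: dict, category="hospital"):
    c = np.zeros((len(CATEGORIES), len(LIVING_STATES), 2, N_AGES))
    for s, v in per_state.items():
        c[CATEGORIES.index(category), int(s)] = v
    return CostParameters(c)


def test_excess_zero_when_costs_equal_across_states():
    costs = _cost_params_by_state({s: 700.0 for s in LIVING_STATES})
    t = identity_table((2020,))
    traj = project(seed_counts(HealthState.CVD, n=10.0), None, t, 2020, 2020)
    df = excess_costs(traj, costs, _flat_utility(), "CVD", 2020)
    assert df["healthcare"].abs().max() == pytest.approx(0.0)


def test_excess_cvd_hand_example():
    """CVD cell at 3,000 vs disease-free 700, 10 person-years ->
    2,300 per person-year."""
    costs = _cost_params_by_state({HealthState.CVD: 3000.0,
                                   HealthState.FREE: 700.0})
    t = identity_table((2020,))
    traj = project(seed_counts(HealthState.CVD, n=10.0), None, t, 2020, 2020)
    df = excess_costs(traj, costs, _flat_utility(), "CVD", 2020)
    allages = df[df["band"] == "all"].iloc[0]
    assert allages["healthcare"] == pytest.approx(23_000.0)
    assert allages["healthcare_per_py"] == pytest.approx(2_300.0)
    assert allages["person_years"] == pytest.approx(10.0)


def test_excess_bands_reconcile_and_consistency():
    costs = _cost_params_by_state({HealthState.DEM: 10_000.0,
                                   HealthState.FI: 4_000.0})
    counts = np.zeros((N_STATES, 2, N_AGES))
    counts[int(HealthState.DEM), 0, 50 - AGE_MIN] = 5.0
    counts[int(HealthState.DEM), 1, 85 - AGE_MIN] = 3.0
    t = identity_table((2020,))
    traj = project(counts, None, t, 2020, 2020)
    df = excess_costs(traj, costs, _flat_utility(), "DEMENTIA", 2020)
    bands = df[df["band"] != "all"]
    allages = df[df["band"] == "all"].iloc[0]
    assert bands["healthcare"].sum() == pytest.approx(allages["healthcare"],
                                                      abs=1e-6)
    for _, row in df.iterrows():
        if row["person_years"] > 0:
            assert row["healthcare_per_py"] * row["person_years"] \
                == pytest.approx(row["healthcare"], rel=1e-9)
    coi = cost_of_illness(traj, costs, _flat_utility(), "DEMENTIA", 2020)
    assert set(coi["band"]) == {"35-64", "65-79", "80-100", "all"}


def test_zero_prevalence_disease_rejected():
    t = identity_table((2020,))
    traj = project(seed_counts(HealthState.FREE, n=10.0), None, t, 2020, 2020)
    costs = _cost_params_by_state({})
    with pytest.raises(ComparisonError):
        excess_costs(traj, costs, _flat_utility(), "DEMENTIA", 2020)


def test_excess_qaly_loss_uses_counterfactual_utility():
    costs = _cost_params_by_state({})
    util = UtilityParameters(
        norms={(35, "F"): 0.9, (35, "M"): 0.9},
        mult_cvd=0.5, mult_ci=1.0, mult_dementia=1.0, adl_decrement=0.0,
        adl_means={s: 0.0 for s in LIVING_STATES})
    t = identity_table((2020,))
    traj = project(seed_counts(HealthState.CVD, n=10.0), None, t, 2020, 2020)
    df = excess_costs(traj, costs, util, "CVD", 2020, qaly_value=60_000.0)
    allages = df[df["band"] == "all"].iloc[0]
    assert allages["qalys_lost"] == pytest.approx(10 * 0.9 * 0.5)
    assert allages["qaly_loss_value"] == pytest.approx(10 * 0.45 * 60_000.0)


# ---------------------------------------------------------------------------
# PSA

def test_beta_multiplier_percentiles(rng):
    """Central 95% interval of the cost multiplier hits [0.80, 1.20] within
    1% at 100,000 draws."""
    alpha = beta_multiplier_alpha(0.8, 1.2)
    draws = 2.0 * rng.beta(alpha, alpha, 100_000)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    assert lo == pytest.approx(0.80, abs=0.01)
    assert hi == pytest.approx(1.20, abs=0.01)
    assert draws.mean() == pytest.approx(1.0, abs=0.01)


def test_degenerate_interval_fixes_multiplier(rng):
    alpha = beta_multiplier_alpha(1.0, 1.0)
    mult = sample_cost_multipliers(rng, CATEGORIES, alpha)
    assert all(v == 1.0 for v in mult.values())


def test_psa_config_validation():
    with pytest.raises(ValueError):
        PSAConfig(n_draws=1)


def test_psa_deterministic_and_collapsing(fitted):
    """Fixed seed reproduces intervals bit-for-bit; with all variances and
    the multiplier interval degenerate, intervals collapse onto the point."""
    cfg = PSAConfig(n_draws=4, seed=99)
    r1 = fitted.run_psa(cfg)
    r2 = fitted.run_psa(cfg)
    pd.testing.assert_frame_equal(r1.intervals, r2.intervals)

    import copy

    frozen = copy.deepcopy(fitted)
    for lg in frozen.transition_logits.values():
        lg.vcov.iloc[:, :] = 0.0
    collapsed = frozen.run_psa(
        PSAConfig(n_draws=4, seed=1, multiplier_interval=(1.0, 1.0)))
    for _, row in collapsed.intervals.iterrows():
        assert row["lo95"] == pytest.approx(row["point"], rel=1e-9, abs=1e-6)
        assert row["hi95"] == pytest.approx(row["point"], rel=1e-9, abs=1e-6)


def test_psa_qalys_reflect_only_epidemiological_uncertainty(fitted):
    """Cost multipliers do not touch the QALY components."""
    import copy

    frozen = copy.deepcopy(fitted)
    for lg in frozen.transition_logits.values():
        lg.vcov.iloc[:, :] = 0.0
    res = frozen.run_psa(PSAConfig(n_draws=4, seed=2))  # costs vary, epi fixed
    assert res.draws["delta_qalys"].std() == pytest.approx(0.0, abs=1e-9)
    assert res.draws["delta_healthcare"].std() > 0
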