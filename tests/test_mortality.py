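"""Mortality projection, state contrasts and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from carecast.mortality import (
    CalibrationError,
    MortalityInputError,
    build_state_mortality_table,
    calibrate_state_mortality,
    fit_state_mortality,
    project_population_mortality,
)
from carecast.states import AGE_MIN, LIVING_STATES, HealthState
from carecast.synthetic import GroundTruth, PanelConfig, generate_panel, FlagLogit


def _hist(rates_by_year, mids=(52, 62, 72, 82), sexes=("F", "M")):
    rows = []
    for cause in ("CVD", "NONCVD"):
        for mid in mids:
            for sex in sexes:
                for year, rate in rates_by_year(mid):
                    rows.append((cause, sex, f"{mid - 2}-{mid + 2}", mid,
                                 year, rate))
    return pd.DataFrame(rows, columns=["cause", "sex", "age_band", "age_mid",
                                       "year", "rate"])


# ---------------------------------------------------------------------------
# step 1

def test_constant_rates_project_constant():
    hist = _hist(lambda mid: [(y, 0.01) for y in range(2000, 2013)])
    rates = project_population_mortality(hist, horizon=2030)
    np.testing.assert_allclose(rates.rate("CVD", "F", 2030),
                               np.full(66, 0.01), rtol=1e-9)


def test_halving_per_decade_closed_form():
    hist = _hist(lambda mid: [(y, 0.02 * 2 ** (-(y - 2000) / 10))
                              for y in range(2000, 2013)])
    rates = project_population_mortality(hist, horizon=2022)
    last_obs = 0.02 * 2 ** (-1.2)
    # ten years past the last observed year -> half the last observed rate
    got = rates.rate("NONCVD", "M", 2022)[52 - AGE_MIN]
    assert got == pytest.approx(last_obs / 2, rel=1e-9)


def test_projection_monotone_in_age_for_monotone_input():
    hist = _hist(lambda mid: [(y, 0.001 * np.exp(0.08 * (mid - 50)))
                              for y in range(2000, 2013)])
    rates = project_population_mortality(hist, horizon=2025)
    q = rates.rate("CVD", "F", 2025)
    assert np.all(np.diff(q) >= -1e-15)


def test_nonpositive_rates_rejected():
    hist = _hist(lambda mid: [(y, 0.0) for y in range(2000, 2013)])
    with pytest.raises(MortalityInputError):
        project_population_mortality(hist)


def test_too_few_years_rejected():
    hist = _hist(lambda mid: [(y, 0.01) for y in range(2000, 2005)])
    with pytest.raises(MortalityInputError, match="10 historical years"):
        project_population_mortality(hist)


# ---------------------------------------------------------------------------
# step 2

def test_intercept_only_death_mle():
    """20 at-risk, 5 deaths per cause in one stratum -> fitted p = 0.25."""
    rows = []
    for pid in range(20):
        rows.append((pid, 0, 70, 0, int(HealthState.FREE)))
        if pid < 5:
            nxt = int(HealthState.DEATH_CVD)
        elif pid < 10:
            nxt = int(HealthState.DEATH_NONCVD)
        else:
            nxt = int(HealthState.FREE)
        rows.append((pid, 1, 72, 0, nxt))
    panel = pd.DataFrame(rows, columns=["pid", "wave", "age", "male", "state"])
    model = fit_state_mortality(panel)
    for cause in ("CVD", "NONCVD"):
        p = expit(model.full_params[cause]["const"])
        assert p == pytest.approx(0.25, abs=1e-6)


def test_state_odds_recovery(panel50k, truth):
    """Fitted state-flag death coefficients within 95% CIs of truth."""
    model = fit_state_mortality(panel50k)
    name_map = {"has_cvd": "cvd", "has_ci": "ci", "has_fi": "fi"}
    inside = total = 0
    for cause in ("CVD", "NONCVD"):
        fl = truth.mortality_logits[cause]
        for cov, attr in name_map.items():
            est = model.full_params[cause][cov]
            se = np.sqrt(model.vcov[cause].loc[cov, cov])
            total += 1
            inside += abs(est - getattr(fl, attr)) <= 1.96 * se
    assert inside >= total - 1  # allow one marginal miss out of six


def test_uniform_mortality_gives_null_state_effects():
    truth = GroundTruth(mortality_logits={
        "CVD": FlagLogit(-5.0, age=0.09, sex=0.3),
        "NONCVD": FlagLogit(-4.0, age=0.09, sex=0.3)})
    panel = generate_panel(PanelConfig(n_individuals=30_000, seed=9, truth=truth))
    model = fit_state_mortality(panel)
    for cause in ("CVD", "NONCVD"):
        for cov in ("has_cvd", "has_ci", "has_fi"):
            est = model.full_params[cause][cov]
            se = np.sqrt(model.vcov[cause].loc[cov, cov])
            assert abs(est) <= 3 * se, (cause, cov)


def test_no_deaths_in_stratum_raises():
    rows = []
    for pid in range(30):
        rows.append((pid, 0, 55, 1, int(HealthState.FREE)))
        rows.append((pid, 1, 57, 1, int(HealthState.FREE)))
    panel = pd.DataFrame(rows, columns=["pid", "wave", "age", "male", "state"])
    with pytest.raises(MortalityInputError, match="age 50-59"):
        fit_state_mortality(panel)


# ---------------------------------------------------------------------------
# step 3

def test_single_state_calibrates_to_population_rate():
    out = calibrate_state_mortality(0.07, {HealthState.FREE: 2.5},
                                    {HealthState.FREE: 1.0})
    assert out[HealthState.FREE] == pytest.approx(0.07, abs=1e-10)


def test_unit_odds_all_states_share_population_rate():
    states = list(LIVING_STATES)
    out = calibrate_state_mortality(0.03, {s: 1.0 for s in states},
                                    {s: 1 / len(states) for s in states})
    for s in states:
        assert out[s] == pytest.approx(0.03, abs=1e-10)


def test_two_state_mixture_matches_grid_search():
    """Mixture reproduces q_pop to 1e-10 and agrees with an independent
    coarse-to-fine grid search on the offset."""
    odds = {HealthState.FREE: 1.0, HealthState.DEM: 3.0}
    occ = {HealthState.FREE: 0.5, HealthState.DEM: 0.5}
    q = calibrate_state_mortality(0.10, odds, occ)
    mix = 0.5 * q[HealthState.FREE] + 0.5 * q[HealthState.DEM]
    assert mix == pytest.approx(0.10, abs=1e-10)
    assert q[HealthState.DEM] > q[HealthState.FREE]

    base = logit(0.10)
    lo_or = np.log([1.0, 3.0])

    def mixture(k):
        return 0.5 * expit(base + k + lo_or[0]) + 0.5 * expit(base + k + lo_or[1])

    k_grid = 0.0
    for width, step in [(10.0, 1e-2), (2e-2, 1e-4), (2e-4, 1e-6)]:
        ks = np.arange(k_grid - width, k_grid + width, step)
        k_grid = ks[np.argmin(np.abs([mixture(k) - 0.10 for k in ks]))]
    assert expit(base + k_grid) == pytest.approx(q[HealthState.FREE], abs=1e-6)
    assert expit(base + k_grid + np.log(3)) == pytest.approx(
        q[HealthState.DEM], abs=1e-6)


def test_conservation_on_randomized_cells(rng):
    """Occupancy-weighted calibrated mortality equals the population rate to
    1e-10 on 1,000 random cells; ordering follows the odds."""
    states = list(LIVING_STATES)
    for _ in range(1000):
        q_pop = rng.uniform(0.001, 0.5)
        odds = {s: rng.uniform(0.2, 5.0) for s in states}
        occ_raw = rng.dirichlet(np.ones(len(states)))
        occ = dict(zip(states, occ_raw))
        q = calibrate_state_mortality(q_pop, odds, occ)
        mix = sum(occ[s] * q[s] for s in states)
        assert abs(mix - q_pop) < 1e-10
        order = sorted(states, key=lambda s: odds[s])
        qs = [q[s] for s in order]
        assert all(qs[i] <= qs[i + 1] + 1e-12 for i in range(len(qs) - 1))


def test_table_conserves_population_rates(fitted):
    """The assembled per-state mortality table reproduces the projected
    population rates under the anchoring occupancy."""
    occ = fitted.model._occupancy()  # (ages, 2, nliv)
    rates = fitted.population_mortality
    tab = fitted.mortality_table
    for ci, cause in enumerate(("CVD", "NONCVD")):
        for si in range(2):
            yi_t = tab.years.index(2020)
            yi_r = rates.years.index(2020)
            mix = (tab.q_state[ci, si, :, yi_t, :] * occ[:, si, :]).sum(-1)
            np.testing.assert_allclose(mix, rates.q[ci, si, :, yi_r], atol=1e-9)


def test_calibration_error_cases():
    with pytest.raises(CalibrationError):
        calibrate_state_mortality(0.0, {HealthState.FREE: 1.0},
                                  {HealthState.FREE: 1.0})
    with pytest.raises(CalibrationError):
        calibrate_state_mortality(0.1, {HealthState.FREE: 1.0},
                                  {HealthState.FREE: 0.0})
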