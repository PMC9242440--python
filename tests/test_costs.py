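"""Cost estimation: hospital OLS + imputation, two-part models, prescribing,
calibration to external totals, deflation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from carecast.costs import (
    CalibrationError,
    CostEstimationError,
    DeflatorError,
    TwoPartModel,
    calibrate_totals,
    cost_prescribing,
    deflate,
    expected_flat_rate_cost,
    expected_two_part_cost,
    fit_hospital_costs,
    fit_two_part,
)
from carecast.states import HealthState
from carecast.synthetic import FORMULARY, deflator_series


def _flat_model(p_z, amount):
    """Two-part model with constant participation z-score and amount."""
    return TwoPartModel("toy", pd.Series({"const": p_z}),
                        pd.Series({"const": amount}))


# ---------------------------------------------------------------------------
# arithmetic of the expectation operators

def test_zero_participation_zero_cost():
    m = _flat_model(-40.0, 10.0)
    assert expected_two_part_cost(m, 70, 0, HealthState.FREE, 7.76) \
        == pytest.approx(0.0, abs=1e-12)


def test_informal_care_annualization():
    """Certain participation, 10 h/week at 7.76/h -> 4,035.20/year."""
    m = _flat_model(40.0, 10.0)
    assert expected_two_part_cost(m, 70, 0, HealthState.FREE, 7.76) \
        == pytest.approx(4035.20)


def test_negative_conditional_amount_clamped():
    m = _flat_model(40.0, -3.0)
    assert expected_two_part_cost(m, 70, 0, HealthState.FREE, 7.76) == 0.0


def test_flat_rate_residential():
    m = TwoPartModel("res", pd.Series({"const": norm.ppf(0.1)}), None)
    assert expected_flat_rate_cost(m, 70, 0, HealthState.FREE, 39_156.0) \
        == pytest.approx(3915.60)


def test_flat_rate_daycare_full_participation():
    m = TwoPartModel("day", pd.Series({"const": 40.0}), None)
    assert expected_flat_rate_cost(m, 70, 0, HealthState.FREE, 7_280.0) \
        == pytest.approx(7280.0)


# ---------------------------------------------------------------------------
# prescribing

def test_prescribing_sums_matched_costs():
    assert cost_prescribing([]) == 0.0
    table = {"A": 30.0, "B": 12.0}
    assert cost_prescribing(["A", "B"], table) == pytest.approx(42.0)


def test_prescribing_unknown_code_uses_default(caplog):
    table = {"A": 30.0}
    with caplog.at_level("WARNING", logger="carecast.costs"):
        assert cost_prescribing(["A", "ZZ"], table) == pytest.approx(30.0)
    assert any("ZZ" in r.message for r in caplog.records)


def test_prescribing_empty_table_rejected():
    with pytest.raises(CostEstimationError):
        cost_prescribing(["A"], {})


# ---------------------------------------------------------------------------
# deflation

def test_deflate_identity_and_ratio():
    d = deflator_series()
    assert deflate(100.0, 2019, d) == pytest.approx(100.0)
    ratio = (d.set_index("year")["index"][2019]
             / d.set_index("year")["index"][2017])
    assert deflate(100.0, 2017, d) == pytest.approx(100.0 * ratio)


def test_deflate_composition():
    d = deflator_series()
    via_b = deflate(deflate(100.0, 2010, d, to_price_year=2015), 2015, d)
    direct = deflate(100.0, 2010, d)
    assert via_b == pytest.approx(direct, rel=1e-12)


def test_deflate_missing_year():
    with pytest.raises(DeflatorError):
        deflate(1.0, 1980, deflator_series())


# ---------------------------------------------------------------------------
# calibration to external totals

def test_calibration_factors():
    modelled = pd.DataFrame({"band": ["35-49", "50-64"], "total": [10.0, 20.0]})
    external = pd.DataFrame({"band": ["35-49", "50-64"], "total": [10.0, 40.0]})
    f = calibrate_totals(modelled, external)
    assert f["35-49"] == pytest.approx(1.0)
    assert f["50-64"] == pytest.approx(2.0)


def test_calibration_recomputation_and_idempotence(rng):
    bands = [f"b{i}" for i in range(5)]
    modelled = pd.DataFrame({"band": bands, "total": rng.uniform(1, 100, 5)})
    external = pd.DataFrame({"band": bands, "total": rng.uniform(1, 100, 5)})
    f = calibrate_totals(modelled, external)
    scaled = modelled.assign(total=modelled["total"] * f.loc[bands].to_numpy())
    np.testing.assert_allclose(scaled["total"].to_numpy(),
                               external["total"].to_numpy(), rtol=1e-9)
    f2 = calibrate_totals(scaled, external)
    np.testing.assert_allclose(f2.to_numpy(), 1.0, rtol=1e-9)


def test_calibration_zero_modelled_band_rejected():
    modelled = pd.DataFrame({"band": ["a"], "total": [0.0]})
    external = pd.DataFrame({"band": ["a"], "total": [5.0]})
    with pytest.raises(CalibrationError):
        calibrate_totals(modelled, external)


# ---------------------------------------------------------------------------
# estimation on the synthetic panel

def test_hospital_cost_state_effect_recovery(panel20k, truth):
    """The +2,000 CVD effect (and the other truth coefficients) are
    recovered within their 95% CIs."""
    model = fit_hospital_costs(panel20k)
    name_map = {"const": "intercept", "age_c": "age", "male": "sex",
                "has_cvd": "cvd", "has_ci": "ci", "has_fi": "fi"}
    inside = total = 0
    for cov, attr in name_map.items():
        est = model.params[cov]
        se = np.sqrt(model.vcov.loc[cov, cov])
        total += 1
        inside += abs(est - getattr(truth.costs.hospital_mean, attr)) <= 1.96 * se
    assert inside >= total - 1
    assert model.params["has_cvd"] == pytest.approx(2000.0, abs=350.0)


def test_hospital_imputation_fills_nonconsenters(panel20k):
    model = fit_hospital_costs(panel20k)
    filled = model.impute(panel20k)
    assert filled.notna().all()
    obs = panel20k["hospital_cost"].notna()
    np.testing.assert_allclose(filled[obs], panel20k.loc[obs, "hospital_cost"])


def test_identical_costs_give_flat_model():
    rows = []
    for pid in range(200):
        state = int(HealthState.CVD) if pid % 2 else int(HealthState.FREE)
        rows.append((pid, 0, 60 + pid % 20, (pid // 2) % 2, state, 500.0))
    panel = pd.DataFrame(rows, columns=["pid", "wave", "age", "male",
                                        "state", "hospital_cost"])
    model = fit_hospital_costs(panel)
    assert model.params["const"] == pytest.approx(500.0, abs=1e-6)
    for cov in model.params.index:
        if cov != "const":
            assert model.params[cov] == pytest.approx(0.0, abs=1e-6)


def test_low_consent_logs_warning(caplog, truth):
    import dataclasses

    from carecast.synthetic import PanelConfig, generate_panel

    low = dataclasses.replace(truth, consent_rate=0.3)
    panel = generate_panel(PanelConfig(n_individuals=1000, seed=6, truth=low))
    with caplog.at_level("WARNING", logger="carecast.costs"):
        fit_hospital_costs(panel)
    assert any("consent share" in r.message for r in caplog.records)


def test_two_part_expected_cost_recovery(panel50k, truth):
    """Estimated expected weekly hours within 5% of the generative truth at
    a mid-range covariate cell (n=50,000)."""
    model = fit_two_part(panel50k, "homecare_hours", "homecare")
    tp = truth.costs.homecare
    for state, age, male in [(HealthState.FI, 75, 0),
                             (HealthState.CVD_FI, 80, 1)]:
        est = float(np.squeeze(expected_two_part_cost(
            model, age, male, state, unit_cost=1.0, weeks=1)))
        p = norm.cdf(tp.participation.linpred(age, male, state))
        m, s = float(tp.amount.linpred(age, male, state)), tp.amount_sd
        c = 0.1  # generative floor on positive amounts
        z = (c - m) / s
        e_amt = c * norm.cdf(z) + m * (1 - norm.cdf(z)) + s * norm.pdf(z)
        tru = p * e_amt
        assert abs(est - tru) / tru < 0.05, state
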