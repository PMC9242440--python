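"""EQ-5D utilities per (state, age, sex) cell and QALY accounting.

The utility of a cell is the population-norm EQ-5D index for its age band
and sex, multiplied by disease-specific multipliers (CVD; cognitive
impairment; dementia, which supersedes the CI multiplier), with an additive
decrement of -0.042 per ADL limitation applied to the state's expected ADL
count, clamped to the admissible EQ-5D range [-0.594, 1]. QALYs for a year
are the utility-weighted count of the living population; death states
contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import AGE_MAX, AGE_MIN, LIVING_STATES, SEXES, HealthState
from .synthetic import DEFAULT_ADL_MEANS, DEFAULT_NORMS

EQ5D_MIN = -0.594
EQ5D_MAX = 1.0

ADL_DECREMENT = -0.042  # EQ-5D index change per ADL limitation


class UtilityInputError(ValueError):
    pass


@dataclass(frozen=True)
class UtilityParameters:
    """Norms by (band start, sex), disease multipliers, ADL decrement and the
    expected ADL count per state.

    ``adl_additive`` applies the ADL decrement additively after the
    multiplicative disease adjustment (default); set False for a fully
    multiplicative reading.
    """

    norms: dict = field(default_factory=lambda: dict(DEFAULT_NORMS))
    mult_cvd: float = 0.91
    mult_ci: float = 0.81
    mult_dementia: float = 0.68
    adl_decrement: float = ADL_DECREMENT
    adl_means: dict = field(default_factory=lambda: dict(DEFAULT_ADL_MEANS))
    adl_additive: bool = True
    compose_cvd_dementia: bool = True  # CVD and dementia multipliers multiply

    def norm(self, age: float, sex: str) -> float:
        bands = sorted({b for b, _ in self.norms})
        band = bands[0]
        for b in bands:
            if age >= b:
                band = b
        try:
            return self.norms[(band, sex)]
        except KeyError:
            raise UtilityInputError(f"no norm for band {band}, sex {sex}") from None


def state_utility(age: float, sex: str, state: HealthState,
                  params: UtilityParameters) -> float:
    """EQ-5D utility for one (age, sex, state) cell."""
    if state.is_death:
        return 0.0
    u0 = params.norm(age, sex)
    mult = 1.0
    if state.has_cvd:
        mult *= params.mult_cvd
    if state.has_dementia:
        mult *= params.mult_dementia
        if not params.compose_cvd_dementia and state.has_cvd:
            mult = params.mult_dementia  # dementia alone governs
    elif state.has_ci:
        mult *= params.mult_ci
    e_adl = params.adl_means.get(state, 0.0)
    if params.adl_additive:
        u = u0 * mult + params.adl_decrement * e_adl
    else:
        u = u0 * mult * max(1.0 + params.adl_decrement * e_adl, 0.0)
    return float(np.clip(u, EQ5D_MIN, EQ5D_MAX))


def utility_grid(params: UtilityParameters) -> np.ndarray:
    """Utilities over (living state, sex, age 35..100)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    out = np.zeros((len(LIVING_STATES), len(SEXES), ages.size))
    for s in LIVING_STATES:
        for si, sex in enumerate(SEXES):
            out[int(s), si] = [state_utility(a, sex, s, params) for a in ages]
    return out


def qalys_for_year(counts: np.ndarray, params: UtilityParameters) -> float:
    """QALYs for one year given living-state counts (n_living, 2, n_ages)."""
    if np.any(counts < 0):
        raise UtilityInputError("negative population counts")
    return float((counts * utility_grid(params)).sum())
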