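"""Health-state space for the ageing multi-state Markov model.

Eight living states defined by three binary morbidity flags — cardiovascular
disease (CVD), cognitive impairment (CI) and functional impairment (FI) —
with dementia defined as concurrent cognitive and functional impairment,
plus two absorbing death states split by cause (CVD vs non-CVD death).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

AGE_MIN = 35
AGE_MAX = 100
AGES = list(range(AGE_MIN, AGE_MAX + 1))

SEXES = ("F", "M")


class HealthState(enum.IntEnum):
    """Model health states. Integer values index the transition matrices."""

    FREE = 0          # free of CVD, CI and FI
    CVD = 1
    CI = 2            # cognitive impairment only
    FI = 3            # functional impairment only
    CVD_CI = 4
    CVD_FI = 5
    DEM = 6           # dementia = CI and FI
    CVD_DEM = 7
    DEATH_CVD = 8
    DEATH_NONCVD = 9

    @property
    def has_cvd(self) -> bool:
        return self in (HealthState.CVD, HealthState.CVD_CI,
                        HealthState.CVD_FI, HealthState.CVD_DEM)

    @property
    def has_ci(self) -> bool:
        return self in (HealthState.CI, HealthState.CVD_CI,
                        HealthState.DEM, HealthState.CVD_DEM)

    @property
    def has_fi(self) -> bool:
        return self in (HealthState.FI, HealthState.CVD_FI,
                        HealthState.DEM, HealthState.CVD_DEM)

    @property
    def has_dementia(self) -> bool:
        return self.has_ci and self.has_fi

    @property
    def is_death(self) -> bool:
        return self in (HealthState.DEATH_CVD, HealthState.DEATH_NONCVD)


LIVING_STATES = tuple(s for s in HealthState if not s.is_death)
DEATH_STATES = (HealthState.DEATH_CVD, HealthState.DEATH_NONCVD)
N_STATES = len(HealthState)
N_LIVING = len(LIVING_STATES)


class TransitionKind(str, enum.Enum):
    """The four incident transitions estimated from panel data."""

    CVD_ONSET = "cvd_onset"
    CI_ONSET = "ci_onset"
    FI_ONSET = "fi_onset"
    FI_RECOVERY = "fi_recovery"


def _with_cvd(s: HealthState) -> HealthState:
    return {HealthState.FREE: HealthState.CVD,
            HealthState.CI: HealthState.CVD_CI,
            HealthState.FI: HealthState.CVD_FI,
            HealthState.DEM: HealthState.CVD_DEM}[s]


def _with_ci(s: HealthState) -> HealthState:
    # acquiring CI on top of FI produces dementia
    return {HealthState.FREE: HealthState.CI,
            HealthState.CVD: HealthState.CVD_CI,
            HealthState.FI: HealthState.DEM,
            HealthState.CVD_FI: HealthState.CVD_DEM}[s]


def _with_fi(s: HealthState) -> HealthState:
    return {HealthState.FREE: HealthState.FI,
            HealthState.CVD: HealthState.CVD_FI,
            HealthState.CI: HealthState.DEM,
            HealthState.CVD_CI: HealthState.CVD_DEM}[s]


def _without_fi(s: HealthState) -> HealthState:
    return {HealthState.FI: HealthState.FREE,
            HealthState.CVD_FI: HealthState.CVD}[s]


def permitted_transitions() -> dict[HealthState, dict[TransitionKind, HealthState]]:
    """Permitted incident transitions out of each living state.

    Onset only for CVD and CI; FI onset and recovery both permitted; at most
    one impairment acquired per cycle; dementia (CI∧FI) is not reversible, so
    FI recovery is only available before CI is present. Death transitions are
    handled by the mortality model, not listed here.
    """
    graph: dict[HealthState, dict[TransitionKind, HealthState]] = {}
    for s in LIVING_STATES:
        moves: dict[TransitionKind, HealthState] = {}
        if not s.has_cvd:
            moves[TransitionKind.CVD_ONSET] = _with_cvd(s)
        if not s.has_ci:
            moves[TransitionKind.CI_ONSET] = _with_ci(s)
        if not s.has_fi:
            moves[TransitionKind.FI_ONSET] = _with_fi(s)
        if s.has_fi and not s.has_dementia:
            moves[TransitionKind.FI_RECOVERY] = _without_fi(s)
        graph[s] = moves
    return graph


PERMITTED = permitted_transitions()

#: Living states at risk of each transition kind (the estimation risk sets).
RISK_SETS: dict[TransitionKind, tuple[HealthState, ...]] = {
    kind: tuple(s for s in LIVING_STATES if kind in PERMITTED[s])
    for kind in TransitionKind
}


@dataclass(frozen=True)
class StateRemap:
    """Counterfactual state remapping used for excess-cost attribution."""

    disease: str
    mapping: dict[HealthState, HealthState]

    def affected_states(self) -> tuple[HealthState, ...]:
        return tuple(sorted(self.mapping, key=int))


#: Dementia counterfactual: the same people as if they only had FI.
REMAP_DEMENTIA = StateRemap(
    "DEMENTIA",
    {HealthState.DEM: HealthState.FI,
     HealthState.CVD_DEM: HealthState.CVD_FI},
)

#: CVD counterfactual: the same people without CVD, other disability fixed.
REMAP_CVD = StateRemap(
    "CVD",
    {HealthState.CVD: HealthState.FREE,
     HealthState.CVD_CI: HealthState.CI,
     HealthState.CVD_FI: HealthState.FI,
     HealthState.CVD_DEM: HealthState.DEM},
)

DISEASE_REMAPS = {"CVD": REMAP_CVD, "DEMENTIA": REMAP_DEMENTIA}
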