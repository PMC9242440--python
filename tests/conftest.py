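import numpy as np
import pandas as pd
import pytest

from carecast import CareTrajectoryModel, GroundTruth, PanelConfig, generate_panel
from carecast.states import HealthState


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def panel20k(truth):
    return generate_panel(PanelConfig(n_individuals=20_000, seed=11, truth=truth))


@pytest.fixture(scope="session")
def panel50k(truth):
    return generate_panel(PanelConfig(n_individuals=50_000, seed=42, truth=truth))


@pytest.fixture(scope="session")
def fitted():
    """Fully fitted results on the default synthetic study conditions."""
    return CareTrajectoryModel.from_synthetic(seed=1, n_individuals=20_000).fit()


def hand_panel(n_at_risk, events, age=70, male=0,
               from_state=HealthState.FREE, to_state=HealthState.CVD):
    """Two-wave panel with a single covariate pattern: ``events`` of
    ``n_at_risk`` move from ``from_state`` to ``to_state``."""
    rows = []
    for pid in range(n_at_risk):
        rows.append((pid, 0, age, male, int(from_state)))
        nxt = int(to_state) if pid < events else int(from_state)
        rows.append((pid, 1, age + 2, male, nxt))
    df = pd.DataFrame(rows, columns=["pid", "wave", "age", "male", "state"])
    df["adl_count"] = 0
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
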