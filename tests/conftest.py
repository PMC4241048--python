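import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import imorsens as im
from imorsens.trial_data import CellCounts, TrialTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def iquit_treatment_table() -> TrialTable:
    """Treatment arm of the worked-example cessation trial (control empty)."""
    from imorsens.examples import iquit_treatment_arm

    return iquit_treatment_arm()


@pytest.fixture
def full_table() -> TrialTable:
    """A complete two-arm table: the worked example's treatment arm plus a
    plausible control arm, so that full fits are possible."""
    cells = {
        (0, 1): CellCounts(41, 24, 66),
        (1, 1): CellCounts(230, 56, 460),
        (0, 0): CellCounts(50, 30, 40),
        (1, 0): CellCounts(180, 90, 300),
    }
    return TrialTable(cells, has_x=True)


def random_table(rng: np.random.Generator, *, max_miss: int = 60) -> TrialTable:
    """Random interior table (no boundary observed cells)."""
    cells = {
        k: CellCounts(
            int(rng.integers(5, 80)),
            int(rng.integers(5, 80)),
            int(rng.integers(0, max_miss)),
        )
        for k in [(0, 0), (1, 0), (0, 1), (1, 1)]
    }
    return TrialTable(cells, has_x=True)


@pytest.fixture
def finite_sim_config() -> im.SimConfig:
    """Generative configuration with informative (finite, nonzero) log
    IMORs, used by the variance/recovery simulations."""
    return im.SimConfig(
        log_imors=im.SensitivityParameters.with_x(0.5, -0.3, 0.2, 0.8)
    )
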