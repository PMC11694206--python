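import numpy as np
import pytest

from sprintwindow import FilterConfig, SpeedTrace, simulate_cohort, study_roster
from sprintwindow.synthetic_data import SimConfig

#: Master seed for every seeded fixture in the suite.
SUITE_SEED = 1234


def make_trace(speeds, position="CM", player_id="P01", match_id="M1", t0_ms=0):
    """Build a gap-free 10 Hz trace from a plain speed list."""
    speeds = np.asarray(speeds, dtype=float)
    t = t0_ms + 100 * np.arange(speeds.size, dtype=np.int64)
    return SpeedTrace(
        player_id=player_id, match_id=match_id, position=position,
        t_ms=t, v_kmh=speeds,
    )


@pytest.fixture
def filter_cfg():
    return FilterConfig()


@pytest.fixture
def small_sim_cfg():
    """Short (10-minute) simulator setup for fast per-trace tests."""
    return SimConfig(duration_s=600.0, n_sprints=2)


@pytest.fixture(scope="session")
def cohort90():
    """Full-scale seeded cohort: the 90-observation study roster at defaults."""
    return simulate_cohort(SimConfig(), study_roster(), seed=SUITE_SEED)
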