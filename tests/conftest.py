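import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectragrow as sg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    return sg.GrowthParameters()


@pytest.fixture
def constant_env():
    """Five days of constant light/temperature/CO2 (one segment per day)."""
    return sg.EnvironmentSchedule.from_segments(
        [
            {"t_start_h": 24 * d, "t_end_h": 24 * (d + 1), "T_C": 23.0,
             "CO2_ppm": 410.0, "I_W_m2": 35.0}
            for d in range(5)
        ]
    )


@pytest.fixture
def day_night_env():
    """Two days with a 20-h photoperiod (4 h dark)."""
    segs = []
    for d in range(2):
        segs.append({"t_start_h": 24 * d, "t_end_h": 24 * d + 20, "T_C": 22.0,
                     "CO2_ppm": 402.0, "I_W_m2": 33.0})
        segs.append({"t_start_h": 24 * d + 20, "t_end_h": 24 * (d + 1), "T_C": 20.0,
                     "CO2_ppm": 402.0, "I_W_m2": 0.0})
    return sg.EnvironmentSchedule.from_segments(segs)


@pytest.fixture
def seedling():
    return sg.PlantState(x_nsdm=0.005, x_sdm=0.045)


@pytest.fixture
def rng():
    return np.random.default_rng(20230523)
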