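import numpy as np
import pandas as pd
import pytest

from hyporheic.simulate import (
    CommunityScenario,
    GroupProfile,
    ThermalScenario,
    simulate_community,
    simulate_temperature,
)


@pytest.fixture(scope="session")
def conduction_series():
    """Noise-free pure-conduction lance (v = 0)."""
    scenario = ThermalScenario(
        velocity_v=0.0,
        sensor_depths_cm=(-2.5, 2.5, 12.5, 22.5, 32.5),
        noise_sd=0.0,
        duration_days=4,
        seed=0,
    )
    return scenario, simulate_temperature(scenario)


@pytest.fixture(scope="session")
def small_community():
    """Small planted-boundary community (both conditions, 6 reps/stratum)."""
    scenario = CommunityScenario(
        site_conditions={
            "U1": "UW", "U2": "UW", "U3": "UW",
            "D1": "DW", "D2": "DW", "D3": "DW",
        },
        n_dates=2,
        groups={
            "invertebrate": GroupProfile(50.0, 0.01),
            "ciliate": GroupProfile(40.0, 0.01),
            "flagellate": GroupProfile(15.0, 0.01),
        },
        dw_multiplier=1.0,
        turnover_sharpness=4.0,
        seed=42,
    )
    return scenario, simulate_community(scenario)
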