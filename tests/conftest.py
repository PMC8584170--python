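import numpy as np
import pytest

from nkscreen import SimulationConfig, join_layout, simulate_plate


@pytest.fixture
def noiseless_config():
    """Ideal-chemistry plate: no noise, no basal consumption, no degradation."""
    return SimulationConfig(
        seed=0, noise_cv=0.0, basal_consumption=0.0, atp_degradation=0.0
    )


@pytest.fixture
def default_plate():
    """One simulated plate at the default study conditions, joined to layout."""
    config = SimulationConfig(seed=42)
    layout, reading, truth = simulate_plate(config)
    return config, join_layout(reading, layout), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
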