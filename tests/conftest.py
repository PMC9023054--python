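import numpy as np
import pytest

from dualsource import (RWParams, ScheduleConfig, generate_schedule,
                        sample_trials, simulate_choices)


@pytest.fixture(scope="session")
def default_config():
    return ScheduleConfig(seed=11)


@pytest.fixture(scope="session")
def default_trials(default_config):
    """One realised 120-trial session (no choices)."""
    return sample_trials(generate_schedule(default_config), seed=7)


@pytest.fixture(scope="session")
def agent_trials(default_trials):
    """Session with choices simulated from a mid-range agent."""
    params = RWParams(alpha_primary_stable=0.2, alpha_primary_volatile=0.3,
                      alpha_secondary_stable=0.15, alpha_secondary_volatile=0.25,
                      zeta=0.4, beta=5.0)
    return params, simulate_choices(params, default_trials, seed=13)
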