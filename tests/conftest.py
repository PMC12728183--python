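import numpy as np
import pytest

from cuelens.agents import AgentParams, simulate_study
from cuelens.environment import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def matching_study():
    """Moderate-size simulated study with probability-matching agents,
    shared across tests that only read it."""
    return simulate_study(
        40, AgentParams(policy="matching_learner"), seed=424242
    )


@pytest.fixture
def decoy_config():
    return SessionConfig(condition="decoy", assigned_predictivity=0.6, seed=7)
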