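import numpy as np
import pandas as pd
import pytest

from patchforage import agents, models
from patchforage.task import PatchDynamicsParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return PatchDynamicsParams()


@pytest.fixture(scope="session")
def session_trials():
    """One full simulated session from a mid-range agent, with RTs."""
    return agents.simulate_participant(agents.AgentParams(), rng=20240101)


@pytest.fixture(scope="session")
def choice_data(session_trials):
    return models.prepare_choice_data(session_trials)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with default planted effects."""
    spec = agents.CohortSpec(n_participants=12)
    return agents.generate_cohort(spec, np.random.default_rng(77))
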