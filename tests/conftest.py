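import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ethosim import (
    RunConfig,
    TrajectoryModel,
    default_ground_truth,
    make_real_like_sessions,
)


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def real_sessions(truth):
    """The stand-in real dataset: 2 LoS + 2 NLoS sessions of 3000 frames."""
    return make_real_like_sessions(truth, n_los=2, n_nlos=2, T=3000, seed=0)


@pytest.fixture(scope="session")
def fitted(real_sessions):
    """A model calibrated once on the fixture dataset, shared across tests."""
    return TrajectoryModel(real_sessions, RunConfig()).fit()
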