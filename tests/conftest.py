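import numpy as np
import pytest

from neurongame import AgentHyperParams, GameConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return AgentHyperParams()


@pytest.fixture
def tiny_config():
    """Small, fast game for closed-loop tests."""
    return GameConfig(trials_per_batch=3, n_batches=2, max_steps_per_trial=600)
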