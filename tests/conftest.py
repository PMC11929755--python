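import numpy as np
import pytest

import morphoca as mc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small grid, full-width network — cheap but architecturally faithful."""
    return mc.ModelConfig(height=9, width=9)


@pytest.fixture
def mini_config():
    """Tiny grid AND tiny network, for oracle/gradient checks."""
    return mc.ModelConfig(height=9, width=9, hidden1=7, hidden2=5)


@pytest.fixture
def mini_params(mini_config, rng):
    """Random nonzero update rule on the tiny network (active dynamics)."""
    params = mc.UpdateRuleParams.initialise(mini_config, rng)
    params.w3 = rng.normal(0.0, 0.1, params.w3.shape).astype(np.float32)
    params.b3 = rng.normal(0.0, 0.02, params.b3.shape).astype(np.float32)
    return params


@pytest.fixture
def tiny_env(tiny_config):
    # slightly reduced offset: at 9x9 the default 0.9 puts the organizer
    # a fraction of a pixel off-grid
    return mc.make_environment(9, 9, 0.0, organizer_offset=0.85, config=tiny_config)
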