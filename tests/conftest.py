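import numpy as np
import pytest

from parbkymo import SimConfig
from parbkymo.synthetic import CondensationScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Short noisy simulation used by integration-style tests."""
    return SimConfig(n_frames=300, rng_seed=7)


@pytest.fixture
def pinned_config():
    cfg = SimConfig(n_frames=600, rng_seed=11)
    cfg.condensation = CondensationScenario(mode="pinned", onset_frame=150)
    return cfg
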