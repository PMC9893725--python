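import numpy as np
import pytest

from ustrack.synth import SyntheticConfig, simulate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated sequence shared by read-only tests."""
    cfg = SyntheticConfig(seed=7, n_frames=40)
    return simulate_sequence(cfg)
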