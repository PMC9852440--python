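import numpy as np
import pytest

from twinconfound import TwinSimConfig, simulate_univariate_twins


@pytest.fixture(scope="session")
def big_additive_pairs():
    """20k+20k pair cohort with a2=0.43, c2=0, shared across recovery tests."""
    cfg = TwinSimConfig(n_mz=20000, n_dz=20000, a2=0.43, c2=0.0, e2=0.57, seed=7)
    return simulate_univariate_twins(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
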