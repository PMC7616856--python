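import numpy as np
import pytest

from gammalink.config import SynthConfig
from gammalink.synthdata import gen_session


@pytest.fixture(scope="session")
def small_session():
    """One shared synthetic session (60 trials, seeded)."""
    return gen_session(SynthConfig(seed=7, n_trials=60))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
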