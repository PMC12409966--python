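import numpy as np
import pytest
from hypothesis import settings

from ledspec import make_default_instrument

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def quiet_instrument():
    """Rainbow instrument with measurement noise off (deterministic reads)."""
    return make_default_instrument("rainbow", seed=0, noise_sd_abs=0.0)


@pytest.fixture
def noisy_instrument():
    """Rainbow instrument with the default read noise (sd 1e-3 absorbance)."""
    return make_default_instrument("rainbow", seed=0, noise_sd_abs=1.0e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
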