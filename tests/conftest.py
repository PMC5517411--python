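import numpy as np
import pytest

from longdcm.simulate import NoiseSpec, SessionSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_noise():
    """State noise only: no observation noise, no drift."""
    return NoiseSpec(obs_amp=0.0, drift_amp=0.0)


@pytest.fixture
def random_series(rng):
    """A nondescript 3-region series for estimator/oracle comparisons."""
    data = rng.standard_normal((200, 3)).cumsum(axis=0) * 0.05 + rng.standard_normal((200, 3))
    return SessionSeries(data=data, tr=2.0, region_names=["a", "b", "c"])
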