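import numpy as np
import pytest

from cardiohrv import IBISeries
from cardiohrv.synthetic import SyntheticConfig, generate_recording

#: Four-interval toy series used throughout as a hand-checkable oracle case.
TOY_INTERVALS = [800.0, 850.0, 790.0, 900.0]


@pytest.fixture
def toy_series() -> IBISeries:
    iv = np.asarray(TOY_INTERVALS)
    return IBISeries(intervals=iv, beat_times=np.cumsum(iv) / 1000.0)


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    """60 constant beats at 1000 ms, 800 Hz, no noise or jitter."""
    return SyntheticConfig(
        n_beats=60, mean_rr=1000.0, rr_noise_sd=0.0, lf_amp=0.0, hf_amp=0.0,
        fs=800.0, ao_latency=40.0, ao_jitter_sd=0.0, channel_noise_sd=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_config):
    return generate_recording(noiseless_config)
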