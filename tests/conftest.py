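import numpy as np
import pytest

from emgdecode.features import WindowConfig, make_windows
from emgdecode.synthetic import SyntheticConfig, generate_record


@pytest.fixture
def small_config():
    """A short recording (3 repetitions, compressed timing) for fast tests."""
    return SyntheticConfig(
        n_channels=4,
        n_repetitions=3,
        rep_duration_s=1.0,
        rest_duration_s=0.5,
        noise_sd=0.05,
        seed=7,
        subject_id=1,
        movement_id=2,
    )


@pytest.fixture
def small_record(small_config):
    return generate_record(small_config)


@pytest.fixture
def small_sequence(small_record):
    return make_windows(small_record, WindowConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
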