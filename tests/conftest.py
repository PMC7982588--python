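import numpy as np
import pytest

from ptarmigan_rhythms import (BirdParams, SP_PROTOCOL,
                               build_light_schedule, default_cohort)


@pytest.fixture(scope="session")
def sp_schedule():
    return build_light_schedule(SP_PROTOCOL, 48)


@pytest.fixture(scope="session")
def cohort1():
    """One full default cohort, shared across tests (seed 1)."""
    return default_cohort(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sp_bird_params():
    return BirdParams(bird_id="T1", seed=99, target_daily_range=2.52,
                      ramp_onset_zt=21.0 + 4.0 / 60.0,
                      activity_onset_zt=22.0 + 20.0 / 60.0,
                      nocturnal_peak_zt=11.0 + 5.0 / 60.0,
                      nocturnal_peak_height=0.6)
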