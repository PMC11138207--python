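import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import myocoh as mc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def channel_map():
    return mc.default_channel_map()


@pytest.fixture(scope="session")
def emg_session():
    """One full tracking session, levels 0.45/0.15, with calibration."""
    cfg = mc.SynthSignalConfig(seed=1, extensor_level=0.45, flexor_level=0.15)
    recording, schedule, params = mc.generate_emg_session(cfg)
    calibration = mc.generate_calibration(cfg)
    return cfg, recording, schedule, calibration, params


@pytest.fixture(scope="session")
def coupled_session():
    """One EEG+EMG session with asymmetric coupling (ipsi 2.0, contra 0.0)."""
    cfg = mc.SynthSignalConfig(
        seed=3, ipsilesional_gain=2.0, contralesional_gain=0.0
    )
    eeg, emg, params = mc.generate_coupled_eeg_emg(cfg)
    return cfg, eeg, emg, params


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
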