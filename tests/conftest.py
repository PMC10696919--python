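import numpy as np
import pytest

from emriclean.core_io import EEGRecording, Marker, default_montage
from emriclean.synthetic_data import SimConfig, simulate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def channel_labels(montage):
    return list(montage.positions)


@pytest.fixture(scope="session")
def short_session():
    """60 s default-condition session shared by read-only tests."""
    return simulate_session(SimConfig(duration=60.0, seed=11))


@pytest.fixture(scope="session")
def quiet_session():
    """60 s session with only neural background + alpha (no artifacts)."""
    return simulate_session(
        SimConfig(
            duration=60.0,
            seed=12,
            gradient_amp=0.0,
            bcg_amp=0.0,
            blink_amp=0.0,
            saccade_amp=0.0,
            muscle_amp=0.0,
            pop_amp=0.0,
            motion_amp=0.0,
            bad_channel=None,
        )
    )


def make_recording(data, rate=250.0, labels=None, markers=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"Ch{i}" for i in range(data.shape[0])]
    return EEGRecording(data=data, rate=rate, labels=labels, markers=markers or [])


@pytest.fixture
def sine_recording():
    """31-channel recording carrying a unit 10 Hz sine, 60 s at 250 S/s."""
    t = np.arange(15000) / 250.0
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (31, 1))
    return make_recording(data, labels=list(default_montage().positions))
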