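import numpy as np
import pytest

from stmli.config import GROUPS, TASKS, SimulationConfig
from stmli.io import RawRecording

ALL_CHANNELS = ("Fz", "F3", "F4", "Cz", "C3", "C4", "POz", "P3", "P4", "M1", "M2")


def zero_amplitudes():
    return {g: {t: {"theta": 0.0, "alpha": 0.0, "gamma": 0.0} for t in TASKS} for g in GROUPS}


def no_artifacts():
    return {"blink": 0.0, "emg": 0.0, "spike": 0.0, "saturation": 0.0}


@pytest.fixture
def short_config():
    """Small cohort with short tasks for fast end-to-end runs."""
    return SimulationConfig(
        task_duration_s=8.0,
        n_group_noconc=7,
        n_group_conc=5,
        seed=11,
    )


@pytest.fixture
def clean_config():
    """Background-only session config: no oscillators, no artifacts."""
    return SimulationConfig(
        task_duration_s=10.0,
        band_amplitudes=zero_amplitudes(),
        artifact_rates=no_artifacts(),
        seed=5,
    )


def make_recording(samples, fs=256.0, labels=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if labels is None:
        labels = ALL_CHANNELS[: samples.shape[0]]
    return RawRecording(samples=samples, channel_labels=labels, sampling_rate=fs)


@pytest.fixture
def sine_recording():
    """One 10 s sine at 10 Hz on a single channel."""
    t = np.arange(10 * 256) / 256.0
    return make_recording(50.0 * np.sin(2 * np.pi * 10 * t), labels=("Fz",))
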