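"""Shared fixtures: small deterministic recordings and epoch sets."""

import numpy as np
import pytest
from hypothesis import settings

from plimci.recording import EEGRecording, EpochSet

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid_recording(freq_hz, fs=1000.0, duration=4.0, n_channels=1, phases=None):
    """Pure sinusoid on every channel, optional per-channel phase offsets."""
    t = np.arange(int(duration * fs)) / fs
    phases = np.zeros(n_channels) if phases is None else np.asarray(phases)
    data = np.stack([np.sin(2 * np.pi * freq_hz * t + ph) for ph in phases])
    labels = [f"ch{i}" for i in range(n_channels)]
    return EEGRecording(channel_labels=labels, sampling_rate=fs, data=data)


@pytest.fixture
def sinusoid_factory():
    return sinusoid_recording


def phases_to_epochs(phases):
    """Wrap a phase array (epoch x channel x sample) into a PhaseSeries-like
    bundle for direct pli computations in tests."""
    return np.asarray(phases)


@pytest.fixture
def quadrature_epochs():
    """Two-channel epochs: cos(wt) and cos(wt - pi/2), 10 Hz at 500 Hz."""
    fs, f = 500.0, 10.0
    t = np.arange(int(3 * fs)) / fs
    x = np.cos(2 * np.pi * f * t)
    y = np.cos(2 * np.pi * f * t - np.pi / 2)
    data = np.stack([np.stack([x, y])] * 4)  # 4 identical epochs
    return EpochSet(
        epochs=data, epoch_length=3.0, sampling_rate=fs,
        channel_labels=["a", "b"], kept_epoch_indices=np.arange(4),
    )
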