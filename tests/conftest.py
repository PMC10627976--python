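"""Shared fixtures: tone recordings and small deterministic cohorts."""

import numpy as np
import pytest

from ppafuse import Recording


def tone_recording(freq, fs=250.0, duration=9.0, amplitude=1.0, phase=0.0,
                   n_channels=1, subject_id="tone", label=None):
    """Single-tone recording: amplitude * cos(2 pi f t + phase) per channel."""
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.cos(2 * np.pi * freq * t + phase)
    return Recording(subject_id, np.tile(x, (n_channels, 1)), fs, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noise_recording(rng):
    """White-noise recording at the desk-scale geometry, 3 channels."""
    return Recording("noise", rng.normal(0, 1.0, (3, int(250 * 9))), 250.0)
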