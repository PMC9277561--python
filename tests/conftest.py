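"""Shared fixtures: small synthetic configurations and lean classifier specs.

Simulation sizes here are chosen so the whole suite runs on one CPU in
minutes while keeping each check statistically meaningful; the heavier
study-scale checks live in test_acceptance.py.
"""

import numpy as np
import pytest
from hypothesis import settings

import eegresp as er

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_synth_config():
    """4+4 subjects, 6 channels, 20 s at 200 Hz: fast but structurally complete."""
    return er.SyntheticConfig(
        n_responders=4,
        n_nonresponders=4,
        channel_labels=er.CHANNELS_62[:6],
        fs=200.0,
        duration_s=20.0,
        seed=123,
    )


@pytest.fixture
def lean_spec():
    """Reduced hyperparameter grid for simulation-heavy classifier tests."""
    return er.ClassifierSpec(c_grid=(1.0, 10.0), gamma_grid=(0.5,), inner_folds=2)


@pytest.fixture
def cohort_labels():
    """Study-sized labels: 17 responders, 31 non-responders."""
    return np.array([True] * 17 + [False] * 31)


def make_recording(data, fs=100.0, session="pre", subject="s0"):
    data = np.atleast_2d(np.asarray(data, float))
    labels = er.CHANNELS_62[: data.shape[0]]
    return er.EEGRecording(subject, session, labels, fs, data)
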