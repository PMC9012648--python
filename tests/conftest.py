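"""Shared fixtures: montage, head model, lead fields, small sessions."""

import numpy as np
import pytest

from abrreref.forward import HeadModel, compute_lead_field, fibonacci_source_layer
from abrreref.montage import standard_montage
from abrreref.simulate import Session, SessionConfig
from abrreref.template import default_template


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def source_layer(head):
    return fibonacci_source_layer(head=head)


@pytest.fixture(scope="session")
def recording_leadfield(montage, head, source_layer):
    """Infinity lead field over the 32 scalp+mastoid channels."""
    return compute_lead_field(montage.recording_channels, head, source_layer)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def noiseless_session():
    """One deterministic subject, 200 stimuli at 25/s and 75 dB, no noise."""
    return Session(SessionConfig(
        n_subjects=1, conditions=((25.0, 75.0),), n_stimuli=200, n_trials=1,
        seed=7, noise_enabled=False, amplitude_jitter=0.0, depth_jitter=0.0,
        orientation_jitter_deg=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
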