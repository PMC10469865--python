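"""Shared fixtures: synthetic datasets generated once per session.

All heavy artifacts (planted-recovery dataset, null dataset, calibration
dataset) are session-scoped because several modules and the acceptance
suite reuse them.
"""

import numpy as np
import pytest

from eegasym.features import extract_features
from eegasym.models import ModelConfig, logo_cv
from eegasym.preprocess import preprocess_recording
from eegasym.synthetic import AsymmetryEffect, GeneratorSpec, generate_dataset

#: The single planted ground-truth effect used for recovery checks:
#: (sad, alpha) on pair 7 = (FT7, FT8), log-effect +0.8.
RECOVERY_PAIR = 7
RECOVERY_BAND = "alpha"
RECOVERY_EMOTION = "sad"
RECOVERY_LOG_EFFECT = 0.8


def features_for(spec: GeneratorSpec):
    recordings = generate_dataset(spec)
    segments = []
    for rec in recordings:
        segments.extend(preprocess_recording(rec))
    return extract_features(segments)


@pytest.fixture(scope="session")
def recovery_features():
    """15 subjects, ~216 segments each, single planted (pair 7, alpha, sad)."""
    spec = GeneratorSpec(
        n_subjects=15,
        n_sessions=1,
        trials_per_session_per_emotion=1,
        trial_duration=220.0,
        fs=200.0,
        asymmetry_effects=[
            AsymmetryEffect(RECOVERY_EMOTION, RECOVERY_BAND, RECOVERY_LOG_EFFECT,
                            pairs=[RECOVERY_PAIR])
        ],
        seed=101,
    )
    return features_for(spec)


@pytest.fixture(scope="session")
def recovery_folds(recovery_features):
    """LOGO folds of the sad model on the recovery dataset (reduced grid)."""
    config = ModelConfig(phi_grid=(0.0, 0.5, 1.0), seed=7)
    return logo_cv(recovery_features, RECOVERY_EMOTION, config)


@pytest.fixture(scope="session")
def transfer_features():
    """Fresh 16-subject draw with the same planted effect (transfer target)."""
    spec = GeneratorSpec(
        n_subjects=16,
        n_sessions=1,
        trials_per_session_per_emotion=1,
        trial_duration=120.0,
        fs=200.0,
        asymmetry_effects=[
            AsymmetryEffect(RECOVERY_EMOTION, RECOVERY_BAND, RECOVERY_LOG_EFFECT,
                            pairs=[RECOVERY_PAIR])
        ],
        seed=202,
    )
    return features_for(spec)


@pytest.fixture(scope="session")
def calibration_features():
    """Planted (sad, alpha, all pairs, +0.6) with > 500 sad segments."""
    spec = GeneratorSpec(
        n_subjects=4,
        n_sessions=1,
        trials_per_session_per_emotion=1,
        trial_duration=520.0,
        fs=200.0,
        asymmetry_effects=[AsymmetryEffect("sad", "alpha", 0.6, pairs="all")],
        seed=303,
    )
    return features_for(spec)


@pytest.fixture(scope="session")
def null_features():
    """No planted effects; 8 subjects for the null LOGO control."""
    spec = GeneratorSpec(
        n_subjects=8,
        n_sessions=1,
        trials_per_session_per_emotion=1,
        trial_duration=160.0,
        fs=200.0,
        seed=404,
    )
    return features_for(spec)


@pytest.fixture(scope="session")
def tiny_features():
    """Small four-emotion table for structural checks (2 subjects)."""
    spec = GeneratorSpec(
        n_subjects=2,
        n_sessions=1,
        trials_per_session_per_emotion=2,
        trial_duration=24.0,
        fs=200.0,
        seed=505,
    )
    return features_for(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
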