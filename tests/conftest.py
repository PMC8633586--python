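"""Shared fixtures: synthetic sessions and their derived epochs/features.

Everything is generated at test time from fixed seeds; session-scoped
fixtures are reused across modules to keep the suite fast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from vmibci.features import extract_feature_table
from vmibci.preprocess import extract_epochs, correct_baseline, preprocess_session
from vmibci.synth import SynthConfig, generate_session

warnings.filterwarnings("ignore", message="n_quads are zero")


@pytest.fixture(scope="session")
def small_session():
    """10-block, artifact-light session: 40 imagine epochs at 250 Hz."""
    cfg = SynthConfig(n_blocks=10, blink_rate=0.0, seed=7)
    rec, events = generate_session(cfg, subject=0)
    return cfg, rec, events


@pytest.fixture(scope="session")
def alpha_epochs(small_session):
    """Preprocessed (detrended, 8-13 Hz, no ICA) imagine epochs."""
    _, rec, events = small_session
    return preprocess_session(rec, events, use_ica=False)


@pytest.fixture(scope="session")
def raw_epochs(small_session):
    """Broadband (detrended only) imagine epochs."""
    _, rec, events = small_session
    return extract_epochs(correct_baseline(rec), events)


@pytest.fixture(scope="session")
def feature_table(alpha_epochs):
    """12-dimensional AR feature table of the small session."""
    return extract_feature_table(alpha_epochs)


@pytest.fixture(scope="session")
def strong_features():
    """Large strong-effect dataset: 100 trials per direction, effect_scale 3.

    Used by the decodability checks; left/right is the maximally distinct
    task pair of the generator's envelope profiles.
    """
    cfg = SynthConfig(n_blocks=100, effect_scale=3.0, blink_rate=0.0, seed=123)
    rec, events = generate_session(cfg, subject=0)
    epochs = preprocess_session(rec, events, use_ica=False)
    return extract_feature_table(epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
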