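"""Shared fixtures: synthetic audio is expensive, so build it once."""

import numpy as np
import pytest

from mfvb import acoustics as ac
from mfvb.voicesim import (
    VoiceSpec,
    journal_plan,
    render_pulse_train,
    synthesize_utterance,
)


@pytest.fixture(scope="session")
def perturbed_train():
    """A 5 s pulse train with 5% jitter / 4% shimmer and its ground truth."""
    spec = VoiceSpec(f0_hz=100.0, jitter_pct=5.0, shimmer_pct=4.0, seed=2)
    audio, periods, amps = render_pulse_train(spec, 5.0)
    return spec, audio, periods, amps


@pytest.fixture(scope="session")
def perturbed_track(perturbed_train):
    _, audio, _, _ = perturbed_train
    return ac.track_frames(audio)


@pytest.fixture(scope="session")
def journal_utterance():
    """A 30 s journaling-style utterance with full ground truth."""
    plan = journal_plan(30.0, seed=1)
    audio, truth = synthesize_utterance(plan)
    return plan, audio, truth


@pytest.fixture(scope="session")
def journal_features(journal_utterance):
    _, audio, _ = journal_utterance
    return ac.extract_feature_vector(audio)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
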