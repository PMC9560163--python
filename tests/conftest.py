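"""Shared fixtures: synthetic sessions and a trained detector.

Sessions are generated at the working rate (1250 Hz) with the generator's
default event morphology; the trained CNN32 fixture is session-scoped so
that detection, robustness and interpretability tests share one training
run.
"""

import numpy as np
import pytest

import ripplekit as rk


@pytest.fixture(scope="session")
def default_session():
    """A 240 s default-parameter session used by detector/feature tests."""
    params = rk.GeneratorParams(duration_s=240.0, fs_raw=1250.0, seed=7)
    return rk.generate_session(params)


@pytest.fixture(scope="session")
def train_session():
    """A long session with >= 300 annotated events for training."""
    params = rk.GeneratorParams(duration_s=2304.0, fs_raw=1250.0, seed=11)
    session = rk.generate_session(params)
    assert len(session.ground_truth) >= 300
    return session


@pytest.fixture(scope="session")
def heldout_session():
    """A held-out 600 s session never seen during training."""
    params = rk.GeneratorParams(duration_s=600.0, fs_raw=1250.0, seed=99)
    return rk.generate_session(params)


@pytest.fixture(scope="session")
def trained_cnn32(train_session):
    """CNN32 trained for 200 epochs on the long synthetic session."""
    ds = rk.prepare_dataset(train_session.recording, train_session.ground_truth)
    model = rk.build_model(rk.ArchitectureConfig.cnn32(), seed=0)
    model, history = rk.train(model, ds, rk.TrainingConfig(epochs=200, seed=0))
    assert history["train"][-1] < history["train"][0]
    return model


@pytest.fixture(scope="session")
def heldout_trace(trained_cnn32, heldout_session):
    rec = rk.zscore(heldout_session.recording)
    return rk.predict(trained_cnn32, rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
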