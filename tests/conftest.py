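import numpy as np
import pytest

from preictal import SynthConfig, generate_recording, extract_features, balance_training_set, train


@pytest.fixture(scope="session")
def small_recording():
    """2-channel recording, 10-min pre-ictal blocks, 2:1 imbalance, one hour."""
    cfg = SynthConfig(
        n_channels=2,
        preictal_minutes=10,
        imbalance_ratio=2,
        n_lead_seizures=2,
        seed=7,
        effect_size=2.0,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def hourly_recording():
    """Recording whose pre-ictal hour aligns with hour blocks (strong effect)."""
    cfg = SynthConfig(
        n_channels=2,
        preictal_minutes=60,
        imbalance_ratio=2,
        n_lead_seizures=2,
        seed=3,
        effect_size=3.0,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def hourly_model(hourly_recording):
    feats = extract_features(hourly_recording)
    Xb, yb = balance_training_set(feats.X, hourly_recording.window_labels, seed=0)
    return train(Xb, yb, algorithm="svm", seed=0)


@pytest.fixture()
def blob_data():
    """Well-separated 2-class Gaussian blobs in 4 dimensions."""
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(-2.0, 1.0, (40, 4)), rng.normal(2.0, 1.0, (40, 4))])
    y = np.array([0] * 40 + [1] * 40)
    return X, y
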