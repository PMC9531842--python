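"""Shared fixtures: a seeded synthetic study and small trained models.

The session-scoped ``study`` fixture reproduces the package's reference
conditions once — a 10-minute synthetic recording at default noise, windowed,
standardized, split 3:1, with the canonical classifier trained on it — and is
reused by the integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import neorespire as nr
from neorespire.features import build_windows, clean_and_split, featurize_records


class Study:
    def __init__(self):
        self.protocol = nr.BreathingProtocol(total_duration=600.0)
        self.rfid = nr.RFIDConfig()
        self.timeline = nr.generate_protocol(self.protocol)
        self.stream = nr.simulate_interrogations(self.timeline, self.rfid, seed=1)
        self.frame = featurize_records(self.stream, self.timeline)
        self.windows = build_windows(self.frame, self.timeline)
        self.train_set, self.test_set = clean_and_split(self.windows, seed=2)
        self.model = nr.build_1dcnn(seed=3)
        self.model, self.history = nr.train(
            self.model, self.train_set, None, nr.TrainConfig(seed=3))
        self.cnn_accuracy = float(
            np.mean(self.model.predict(self.test_set.X) == self.test_set.y))


@pytest.fixture(scope="session")
def study() -> Study:
    return Study()


@pytest.fixture()
def tiny_model():
    """A 2-input dense ReLU stack small enough to train in milliseconds."""
    from neorespire.network import Dense, Flatten, NetworkModel

    def build(seed: int = 0) -> NetworkModel:
        return NetworkModel(
            [Flatten(), Dense(8, activation="relu"), Dense(1, activation="sigmoid")],
            input_shape=(2, 1), seed=seed)

    return build


@pytest.fixture()
def separable_xy():
    """Linearly separable two-feature data with a wide margin."""
    rng = np.random.default_rng(42)
    n = 200
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    margin = np.abs(X[:, 0] + X[:, 1]) > 0.4
    return X[margin], y[margin]
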