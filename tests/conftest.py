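"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

import sparkline as sl
from sparkline.detect.nn import DetectorConfig, NeuralSparkDetector


@pytest.fixture(scope="session")
def train_dataset():
    """Desk-scale detector training set: amplitudes uniform over [2, 8] sigma."""
    return sl.generate_detection_set(
        n_images=12, sparks_per_image=6, amp_range_sigma=(2.0, 8.0), seed=11
    )


@pytest.fixture(scope="session")
def trained_detector(train_dataset):
    """One trained neural detector shared across the session (seed 7)."""
    return NeuralSparkDetector(DetectorConfig(seed=7)).fit(train_dataset)


@pytest.fixture(scope="session")
def detection_test_set():
    """Held-out benchmark images, same amplitude law, different seed."""
    return sl.generate_detection_set(
        n_images=16, sparks_per_image=6, amp_range_sigma=(2.0, 8.0), seed=99
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_image(rng):
    """Pure-noise normalized line-scan image, sigma = 0.1."""
    data = 1.0 + rng.normal(0.0, 0.1, (256, 1000))
    return sl.LineScanImage(np.clip(data, 0, None), dx=0.14, dt=2.5, normalized=True)
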