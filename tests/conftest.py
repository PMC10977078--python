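"""Shared fixtures: a small annotated recording, its window dataset, and
session-scoped trained gate/verifier models (training is the slow part, so
every test that needs a fitted model reuses these)."""

import numpy as np
import pytest

from preictal.estimators import QuantizedCNNClassifier
from preictal.synth import SynthConfig, gen_recording
from preictal.windowing import WindowingConfig, extract_windows, label_intervals


@pytest.fixture(scope="session")
def small_windowing():
    return WindowingConfig(
        sph_s=30.0, pil_s=300.0, window_len_s=30.0, preictal_overlap_s=5.0
    )


@pytest.fixture(scope="session")
def small_recording():
    """Three annotated seizures, 4 channels at 64 Hz, strong signature."""
    return gen_recording(
        SynthConfig(
            n_channels=4,
            fs=64.0,
            duration_s=3000.0,
            seizure_onsets_s=(700.0, 1600.0, 2500.0),
            preictal_len_s=330.0,
            signature_gain=2.0,
            noise_sd=1.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_dataset(small_recording, small_windowing):
    rec, cfg = small_recording, small_windowing
    return extract_windows(rec, label_intervals(rec, cfg), cfg)


@pytest.fixture(scope="session")
def trained_cnn(small_dataset):
    return QuantizedCNNClassifier(bits=8, epochs=8, random_state=0).fit(
        small_dataset.windows, small_dataset.labels
    )


@pytest.fixture(scope="session")
def trained_bnn(small_dataset):
    return QuantizedCNNClassifier(
        bits=1, binary=True, epochs=20, random_state=0
    ).fit(small_dataset.windows, small_dataset.labels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
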