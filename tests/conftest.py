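import numpy as np
import pytest

from dacb import ModelConfig, SynthSpec, generate_trialset
from dacb.experiments import prepare_samples


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small but structurally complete model configuration."""
    return ModelConfig(
        n_channels=8,
        n_classes=3,
        conv_filters=8,
        se_reduction=2,
        lstm_units=4,
        fc1_units=8,
        fc2_units=4,
        fusion_width=8,
        seed=13,
        dtype="float64",
    )


@pytest.fixture(scope="session")
def small_trialset():
    """6 subjects x 8 trials of 8-channel data, 3 classes, clean signal."""
    spec = SynthSpec(
        n_subjects=6,
        n_trials_per_subject=8,
        n_channels=8,
        trial_length=120,
        segment_length=40,
        n_classes=3,
        snr=8.0,
        seed=21,
    )
    return generate_trialset(spec)


@pytest.fixture(scope="session")
def small_samples(small_trialset):
    return prepare_samples(small_trialset, segment_length=40)
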