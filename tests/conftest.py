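import numpy as np
import pytest

from driversense.io import EEG_CHANNELS, EEG_RATE_HZ, SignalStream
from driversense.synth import GeneratorConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eeg_noise_stream(rng):
    """4 s of white-noise EEG on the full 14-channel montage."""
    n = int(4 * EEG_RATE_HZ)
    return SignalStream(rng.standard_normal((14, n)), EEG_RATE_HZ,
                        EEG_CHANNELS, "eeg")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthesized cohort shared across tests (manifest is cheap;
    samples are generated lazily per trial)."""
    return gen_dataset(GeneratorConfig(
        n_subjects=3, trials_per_subject=4, incidents_per_subject=4,
        hazardous_per_subject=2, attention_trial_s=4.0, seed=7))
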