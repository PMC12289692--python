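import numpy as np
import pytest

from margineeg import SynthConfig, generate_dataset, preprocess_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A small but realistic synthetic world used by several test modules."""
    return SynthConfig(n_subjects=2, n_trials_per_subject=40, n_channels=6,
                       fs=64.0, erd_factor=0.4, seed=7)


@pytest.fixture(scope="session")
def small_epochs(small_cfg):
    """Preprocessed epochs for two subjects (filter -> segment -> rejection)."""
    return preprocess_dataset(generate_dataset(small_cfg))
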