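import numpy as np
import pytest

from miqfs import EegSpec, TableSpec, gen_eeg_dataset, gen_feature_table


@pytest.fixture(scope="session")
def planted_table():
    """Default planted table (300 x 20: 5 relevant, 3 redundant, 12 irrelevant)."""
    return gen_feature_table(TableSpec(seed=1))


@pytest.fixture(scope="session")
def small_eeg():
    """A small 19-channel epoch set (4 subjects, 2 epochs each, 10 s @ 256 Hz)."""
    return gen_eeg_dataset(EegSpec(n_subjects=4, duration_s=20.0, seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
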