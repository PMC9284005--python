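import numpy as np
import pytest

from hcsnet.eval_baselines import build_window_table
from hcsnet.synthetic_data import ParadigmSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two synthetic subjects, full session each (60 trials total)."""
    manifest, recordings = simulate_dataset(2, variability=0.1, seed=42)
    return manifest, recordings


@pytest.fixture(scope="session")
def small_table(small_dataset):
    _, recordings = small_dataset
    return build_window_table(recordings)


@pytest.fixture(scope="session")
def default_dataset():
    """The 10-subject default-condition dataset (variability 0.1, seed 42)."""
    manifest, recordings = simulate_dataset(10, variability=0.1, seed=42)
    return manifest, recordings


@pytest.fixture(scope="session")
def default_table(default_dataset):
    _, recordings = default_dataset
    return build_window_table(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
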