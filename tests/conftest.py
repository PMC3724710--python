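import numpy as np
import pytest

from mdsfs.attributes import load_default_table
from mdsfs.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by pipeline-level tests."""
    spec = SyntheticSpec(
        n_classes=2, seqs_per_class=30, length_range=(60, 90),
        planted=("H",), effect_size=0.9, seed=11,
    )
    sequences, labels = generate_dataset(spec)
    return sequences, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
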