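import numpy as np
import pytest

from coherostrat import SyntheticSpec, default_montage


@pytest.fixture(scope="session")
def montage19():
    return default_montage("19")


@pytest.fixture(scope="session")
def montage64():
    return default_montage("64")


@pytest.fixture(scope="session")
def small_spec():
    """A 19-channel spec at the reduced sampling rate used for fast tests."""
    return SyntheticSpec(n_subjects=4, montage="19", fs_raw=128.0,
                         duration=200.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
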