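import numpy as np
import pytest

from pepqsar.descriptors import DescriptorScale, EncodingSpec, load_scale
from pepqsar.io import load_orac_table


@pytest.fixture(scope="session")
def z5():
    return load_scale()


@pytest.fixture(scope="session")
def default_encoding():
    return EncodingSpec()


@pytest.fixture(scope="session")
def orac_records():
    return load_orac_table()


@pytest.fixture
def toy_scale():
    """1-dimensional scale: each residue mapped to its alphabet index + 1."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return DescriptorScale("toy1", 1, {aa: (float(i + 1),) for i, aa in enumerate(letters)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
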