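import numpy as np
import pytest

from morphozone.fixtures import (
    tiny_matching_dataset,
    tiny_matching_scheme,
    tiny_object_dataset,
    tiny_object_scheme,
)


@pytest.fixture(scope="session")
def object_scheme():
    return tiny_object_scheme()


@pytest.fixture(scope="session")
def matching_scheme():
    return tiny_matching_scheme()


@pytest.fixture(scope="session")
def tiny_object():
    """12-specimen object-symmetry dataset: (configs, covariates, truth)."""
    return tiny_object_dataset(seed=11)


@pytest.fixture(scope="session")
def tiny_matching():
    """12-specimen matching-symmetry dataset: (configs, covariates, truth)."""
    return tiny_matching_dataset(seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
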