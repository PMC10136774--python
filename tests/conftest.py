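import numpy as np
import pytest

from histocurate import make_separable_patch_set
from histocurate.training import extract_patch_features


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_set():
    """Two-class, cleanly separable patch set shared by training/eval tests."""
    return make_separable_patch_set(200, rng=0)


@pytest.fixture(scope="session")
def separable_features(separable_set):
    return extract_patch_features(separable_set.images)
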