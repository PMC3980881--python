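import numpy as np
import pytest

from cmqa.landscapes import CallableLandscape, planted_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def planted19():
    """The 19-variable validation landscape with five traps."""
    return planted_landscape(19, n_traps=5, rng=np.random.default_rng(123))


@pytest.fixture(scope="session")
def planted4():
    """Small trap-free landscape for fast engine tests."""
    return planted_landscape(4, n_traps=0, rng=np.random.default_rng(7))


@pytest.fixture
def constant_landscape():
    return CallableLandscape(3, lambda a: 5.0)
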