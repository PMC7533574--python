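import numpy as np
import pytest

from fmdwi.acquisition import default_scheme


@pytest.fixture(scope="session")
def scheme():
    """The default 3-Δ × 6-G0 × 3-direction protocol (66 volumes)."""
    return default_scheme()


@pytest.fixture(scope="session")
def cells(scheme):
    return scheme.cells()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
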