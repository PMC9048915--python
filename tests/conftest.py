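import numpy as np
import pytest

from heliovis.templates import measurement_grid, spectral_grid


@pytest.fixture(scope="session")
def grid10():
    """The 300-700 nm / 10 nm interference-filter measurement grid."""
    return measurement_grid()


@pytest.fixture(scope="session")
def grid1():
    """Dense 1 nm evaluation grid."""
    return spectral_grid(300.0, 700.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
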