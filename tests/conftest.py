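import numpy as np
import pytest

from muakit.spectra import WavelengthGrid
from muakit.synthlib import LUNG_REFERENCE_WEIGHTS, make_library


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.canonical()


@pytest.fixture(scope="session")
def library(grid):
    return make_library(grid)


@pytest.fixture(scope="session")
def lung_weights():
    return dict(LUNG_REFERENCE_WEIGHTS)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
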