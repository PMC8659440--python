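import numpy as np
import pytest

import teaspec as ts


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 80-band grid for fast unit tests."""
    return ts.make_wavelength_grid(400.0, 960.0, 80)


@pytest.fixture(scope="session")
def small_library(small_grid):
    return ts.default_library(small_grid)


@pytest.fixture(scope="session")
def chem_default():
    return ts.simulate_kinetics()


@pytest.fixture(scope="session")
def spectra_small(chem_default, small_library):
    """180 spectra on the coarse grid with default noise."""
    return ts.simulate_spectra(chem_default, small_library,
                               ts.NoiseModel(seed=7), replicates=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
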