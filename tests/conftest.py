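import numpy as np
import pytest

import eoseg
from eoseg import PhantomConfig, generate_phantom, generate_training_set

DEFAULT_NOISE_SD = PhantomConfig().noise_sd


@pytest.fixture(scope="session")
def training_set():
    """Default five-class training set: 600 spectra per in-model class."""
    return generate_training_set(seed=0)


@pytest.fixture(scope="session")
def basis(training_set):
    return eoseg.fit_pca(training_set)


@pytest.fixture(scope="session")
def eosinophil_set():
    """Held-out target-class spectra for band selection."""
    return generate_training_set(seed=1, classes=["eosinophil"], n_per_class=300)


@pytest.fixture(scope="session")
def band_pair(basis, eosinophil_set):
    err = eoseg.mean_class_error(basis, eosinophil_set, basis.default_m)
    return eoseg.select_band_pair(err)


@pytest.fixture(scope="session")
def small_scene():
    """A 64×64 phantom for cheap whole-image tests."""
    return generate_phantom(PhantomConfig(height=64, width=64), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
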