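import numpy as np
import pytest
from hypothesis import settings

from fenceflow import generate_covariates, make_fenced_world
from fenceflow.raster import Raster

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stack():
    """Reduced covariate stack on a 40x40 grid (ndvi, twi, one distance layer)."""
    return generate_covariates(
        (40, 40), cell_size=100.0, correlation_length=300.0, seed=7, layers=["ndvi", "twi", "dist_rivers"]
    )


@pytest.fixture(scope="session")
def full_stack():
    """All covariates on a small grid."""
    return generate_covariates((30, 30), cell_size=50.0, correlation_length=200.0, seed=3)


@pytest.fixture(scope="session")
def fenced_world():
    """The constructed severed-corridor study system (shared across tests)."""
    return make_fenced_world(11)


@pytest.fixture
def uniform_raster():
    def make(value=1.0, shape=(10, 10), cell_size=1.0):
        return Raster(np.full(shape, float(value)), cell_size=cell_size, origin=(0.0, shape[0] * cell_size))

    return make
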