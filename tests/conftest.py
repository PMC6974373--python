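import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from planbio.grids import DoseGrid, StructureMask
from planbio.synthetic import PhantomSpec, generate_cohort, generate_phantom

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def cohort15():
    """The default 15-patient cohort, shared across evaluation tests."""
    return generate_cohort(n_patients=15, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_grid_and_mask(rng):
    """A small random dose grid with an irregular mask (voxel-sort oracle fodder)."""
    shape = (21, 19, 17)
    values = rng.gamma(shape=4.0, scale=10.0, size=shape)
    grid = DoseGrid(values, spacing=(2.0, 2.0, 2.0))
    mask = StructureMask("blob", rng.random(shape) < 0.4)
    return grid, mask
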