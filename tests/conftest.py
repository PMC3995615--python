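import numpy as np
import pytest
from hypothesis import settings

from dbmap import (
    StudyRegion,
    UniformDiskReference,
    make_circle_points,
    make_eval_grid,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_disk():
    return StudyRegion.unit_disk()


@pytest.fixture(scope="session")
def uniform_reference(unit_disk):
    return UniformDiskReference(unit_disk)


@pytest.fixture(scope="session")
def coarse_grid(unit_disk):
    """~100-point grid: fast enough for repeated map computation in tests."""
    return make_eval_grid(unit_disk, 11)


@pytest.fixture(scope="session")
def projections20(unit_disk):
    return make_circle_points(unit_disk, 20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
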