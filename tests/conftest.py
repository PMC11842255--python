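import numpy as np
import pytest

from mrinorm import Volume3D
from mrinorm.phantom import PhantomConfig, CohortSpec, generate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_volume(rng):
    return Volume3D(rng.random((12, 14, 10)) * 100.0, spacing_mm=(1.0, 1.0, 2.0))


@pytest.fixture
def box_mask():
    m = np.zeros((12, 14, 10), dtype=np.uint8)
    m[3:9, 4:11, 2:8] = 1
    return m


@pytest.fixture(scope="session")
def two_cohort_manifest(tmp_path_factory):
    """Two small phantom cohorts differing by a 2x gain and +10 offset."""
    cfg = PhantomConfig(
        grid_shape=(24, 24, 24),
        n_subjects_per_cohort=5,
        noise_sigma=2.0,
        seed=11,
        cohorts=[
            CohortSpec("A", gain=1.0, offset=0.0, site="site1", vendor="ge",
                       field_strength="3T", coil="ERC"),
            CohortSpec("B", gain=2.0, offset=10.0, site="site2", vendor="siemens",
                       field_strength="1.5T", coil="nERC"),
        ],
    )
    out = tmp_path_factory.mktemp("cohorts")
    return generate_cohorts(cfg, out)
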