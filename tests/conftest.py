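import numpy as np
import pytest

from scnpipe import cohort, volumes
from scnpipe.volumes import VolumetricMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map(rng):
    values = rng.normal(0.0, 0.1, size=(20, 24, 20))
    return VolumetricMap(
        values=values, spacing_mm=(1.0, 1.0, 1.0), affine=np.eye(4), subject_id="S0001"
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study's default conditions, shared across tests."""
    return cohort.make_cohort(N=200, seed=7)


@pytest.fixture(scope="session")
def default_matrices(default_cohort):
    c = default_cohort
    vm_exp = volumes.build_voxel_matrix(c.maps, c.mask, exponentiate=True)
    vm_log = volumes.build_voxel_matrix(c.maps, c.mask, exponentiate=False)
    return vm_exp, vm_log
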