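import numpy as np
import pytest

from fcdensity.analysis import analyze_cohort
from fcdensity.config import StudyConfig
from fcdensity.core import BoldRun, GridGeometry
from fcdensity.synthetic import default_two_group_spec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom8():
    return GridGeometry.isotropic((8, 8, 8), 3.0)


def random_run(rng, dims=(6, 6, 6), T=50, voxel_mm=3.0, tr_s=2.0):
    geom = GridGeometry.isotropic(dims, voxel_mm)
    return BoldRun(data=rng.standard_normal(dims + (T,)), geometry=geom, tr_s=tr_s)


@pytest.fixture(scope="session")
def planted_cohort():
    """Desk-scale two-group cohort with a local hub and a long-range pair
    planted in group A only (shares 0.8 vs 0.0)."""
    spec = default_two_group_spec(dims=(20, 20, 20), n_per_group=10, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_result(planted_cohort):
    """Full pipeline result on the planted cohort (shared across tests)."""
    return analyze_cohort(
        planted_cohort.subjects, planted_cohort.masks, StudyConfig()
    )
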