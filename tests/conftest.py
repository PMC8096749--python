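import numpy as np
import pytest

from morphkls import SimulationDesign, build_network, simulate_cohort
from morphkls.network import DensityProfile


@pytest.fixture(scope="session")
def small_cohort():
    """Null two-group cohort (no planted effect), desk scale."""
    design = SimulationDesign(n_per_group=4, voxels_per_region=150, seed=11)
    subjects, metas = simulate_cohort(design)
    return subjects, metas


@pytest.fixture(scope="session")
def subject_network(small_cohort):
    subjects, _ = small_cohort
    return build_network(subjects[0])


def profile_pair():
    """The worked two-point example: P = [.5, .5], Q = [.9, .1]."""
    grid = np.array([0.0, 1.0])
    p = DensityProfile("p", grid, np.array([0.5, 0.5]), 1.0)
    q = DensityProfile("q", grid, np.array([0.9, 0.1]), 1.0)
    return p, q


@pytest.fixture
def toy_profiles():
    return profile_pair()
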