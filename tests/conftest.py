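import numpy as np
import pytest

from metahub import make_grid, make_ground_truth, simulate_cohort_maps
from metahub.glm import fit_cohort_glm


@pytest.fixture(scope="session")
def small_grid():
    """10x10x10 all-gray 3-mm grid with 8 contiguous networks."""
    return make_grid((10, 10, 10), voxel_size_mm=3.0, n_networks=8, seed=0)


@pytest.fixture(scope="session")
def planted_truth(small_grid):
    """Strong contiguous hub blob with moderate heterogeneity."""
    return make_ground_truth(
        small_grid,
        hub_centers=[(13.5, 13.5, 13.5)],
        hub_radius_mm=6.0,
        hub_effect=1.0,
        tau2=0.01,
        sigma_within=0.5,
        seed=0,
    )


@pytest.fixture(scope="session")
def planted_cohorts(small_grid, planted_truth):
    return simulate_cohort_maps(small_grid, planted_truth, [20] * 12, seed=11)


@pytest.fixture(scope="session")
def planted_summaries(planted_cohorts):
    return [
        fit_cohort_glm(c.subject_maps, c.ages, c.sexes, c.cohort_id)[0]
        for c in planted_cohorts
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
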