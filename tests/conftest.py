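import numpy as np
import pytest

from boldspect import CohortSpec, ParadigmSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_paradigm() -> ParadigmSpec:
    """Six 20-s task / 15-s rest sessions, TR 2 s, truncated to 60 volumes."""
    return ParadigmSpec()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Tiny noise-free cohort: task voxels carry exactly the evoked regressor."""
    spec = CohortSpec(
        n_group0=2, n_group1=2, grid_shape=(6, 6, 6), n_task_voxels=3,
        n_discriminative_voxels=0, noise_sd=0.0, ar1_coeff=0.0, motion_sd=0.0,
        group_effect=0.0, effect_amplitude=1.0, seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def strong_signal_cohort():
    """Small cohort with a planted 8-voxel discriminative cluster, strong effect."""
    spec = CohortSpec(
        n_group0=8, n_group1=8, grid_shape=(10, 10, 10), n_task_voxels=8,
        n_discriminative_voxels=8, cluster_size=8, group_effect=3.0, seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
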