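"""Shared fixtures: small phantoms and cohorts, generated at test time."""

import numpy as np
import pytest

from adcsurv.synthetic import CohortConfig, generate_cohort

#: grid small enough for fast tests but leaving >1000 voxels after the
#: triple erosion of the brain mask
TEST_GRID = (32, 32, 20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject noisy cohort with volumes, shared across tests."""
    cfg = CohortConfig(n_subjects=10, grid_shape=TEST_GRID, seed=42,
                       noise_sigma=0.03)
    subjects, truth = generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Six-subject noiseless cohort for exact ground-truth checks."""
    cfg = CohortConfig(n_subjects=6, grid_shape=TEST_GRID, seed=7,
                       noise_sigma=0.0)
    subjects, truth = generate_cohort(cfg)
    return cfg, subjects, truth


def head_phantom(shape=(24, 24, 16), value=1000.0):
    """Bright ellipsoid on dark background plus analytic membership mask."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    axes = [0.4 * s for s in shape]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, axes):
        acc = acc + ((g - c) / a) ** 2
    member = acc <= 1.0
    vol = np.where(member, value, 0.0)
    return vol, member
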