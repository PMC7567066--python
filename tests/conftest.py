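"""Shared fixtures: synthetic cohorts at study scale and desk scale."""

import numpy as np
import pytest

from painnet import simulate_study
from painnet.selection import stability_select


@pytest.fixture(scope="session")
def study49():
    """Study-scale cohort: n=49, T=240, K=12 (E=66), 3 planted edges."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def selection49(study49):
    """Stability selection on the study-scale cohort."""
    return stability_select(study49.edge_table, study49.rates, seed=7)


@pytest.fixture(scope="session")
def study_noiseless():
    """Cohort with zero outcome noise and zero visit jitter: the planted
    linear model is exact for unclamped subjects."""
    return simulate_study(seed=3, noise_sd=0.0, vas_jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale cohort small enough for per-test refits (n=14, K=6)."""
    return simulate_study(
        n_subjects=14, n_volumes=80, grid_shape=(9, 9, 9),
        n_components=6, n_planted=1, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
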