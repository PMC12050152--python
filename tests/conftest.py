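import numpy as np
import pytest

import mfcoupling as mfc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across read-only tests."""
    cfg = mfc.CohortConfig(
        n_regions=12,
        n_subjects_per_group=4,
        n_voxels_per_region=300,
        timeseries_length=60,
        n_sites=2,
        seed=7,
    )
    return mfc.generate_cohort(cfg)


def make_msn(values, labels=None):
    values = np.asarray(values, dtype=float)
    return mfc.SimilarityMatrix(
        values=values, region_labels=labels or list(range(1, len(values) + 1))
    )


def make_fcn(values, labels=None):
    values = np.asarray(values, dtype=float)
    return mfc.ConnectivityMatrix(
        values=values, region_labels=labels or list(range(1, len(values) + 1))
    )


def symmetrize(a):
    a = np.asarray(a, dtype=float)
    out = (a + a.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out
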