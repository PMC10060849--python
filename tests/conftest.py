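import numpy as np
import pytest

from brainlayers import CohortConfig, SiteSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def effect_cohort_config():
    """Three-site cohort with five injected edges and mild site effects."""
    return CohortConfig(
        n_rois=20,
        n_timepoints=150,
        sites=[SiteSpec("s1", 17, 17), SiteSpec("s2", 17, 17), SiteSpec("s3", 16, 16)],
        effect_edges=frozenset({(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)}),
        effect_size=0.5,
        site_shift_sd=0.2,
        base_density=0.1,
        seed=5,
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_cohort_config):
    return generate_cohort(effect_cohort_config)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: any group separation is noise."""
    cfg = CohortConfig(
        n_rois=10,
        n_timepoints=100,
        sites=[SiteSpec("s1", 10, 10), SiteSpec("s2", 10, 10), SiteSpec("s3", 10, 10)],
        effect_size=0.0,
        site_shift_sd=0.1,
        base_density=0.1,
        seed=11,
    )
    return generate_cohort(cfg)


def random_symmetric_correlationlike(n, rng):
    """A symmetric matrix with unit diagonal and entries in [−1, 1]."""
    w = rng.uniform(-1.0, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w
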