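import numpy as np
import pytest

from connectoclass import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site toy cohort with a strong planted effect, small enough for
    fast classifier tests (20 regions, 13 controls/site so the confound GP
    can be fitted inside 5-fold CV)."""
    spec = CohortSpec(
        n_regions=20,
        n_timepoints=120,
        n_patients_per_site=13,
        n_controls_per_site=13,
        n_sites=2,
        affected_nodes=(0, 1, 2),
        edge_effect=0.35,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Signal-free single-site cohort: no group, confound or site effects."""
    spec = CohortSpec(
        n_regions=12,
        n_timepoints=100,
        n_patients_per_site=20,
        n_controls_per_site=20,
        n_sites=1,
        edge_effect=0.0,
        confound_slopes=(0.0, 0.0),
        site_shift=0.0,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
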