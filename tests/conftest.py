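import numpy as np
import pytest

import hubspin as hs


@pytest.fixture(scope="session")
def parcellation():
    """62-parcel bilateral sphere (31 per hemisphere)."""
    return hs.build_parcellation(31)


@pytest.fixture(scope="session")
def template(parcellation):
    return hs.generate_template_connectome(parcellation, hs.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_cohort(parcellation):
    """One full synthetic cohort under the default (effectful) config."""
    return hs.simulate_cohort(parcellation, hs.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort(parcellation):
    """A 120-subject cohort for cheaper model-fitting tests."""
    return hs.simulate_cohort(parcellation, hs.CohortConfig(seed=7, n_subjects=120))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
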