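import numpy as np
import pytest

from earlygrowth.pipeline import derive_efw, derive_sds
from earlygrowth.synthetic import SimConfig, simulate_cohort, true_reference_charts


@pytest.fixture(scope="session")
def true_charts():
    return true_reference_charts()


@pytest.fixture(scope="session")
def cohort_mid():
    """Medium synthetic cohort with default study conditions."""
    return simulate_cohort(SimConfig(n_children=1200, seed=42))


@pytest.fixture(scope="session")
def sds_mid(cohort_mid, true_charts):
    """Weight SDS of the medium cohort against the generating charts."""
    efw = derive_efw(cohort_mid.wide)
    return derive_sds(cohort_mid.wide, efw, true_charts)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
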