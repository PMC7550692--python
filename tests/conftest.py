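import numpy as np
import pandas as pd
import pytest

from pdacdriver import CohortParams, build_profiles, generate_cohort
from pdacdriver.mutation_profiles import filter_exonic


@pytest.fixture(scope="session")
def default_cohort_profiles() -> pd.DataFrame:
    """Profiles from one default-parameter synthetic cohort at n=5000."""
    mutations, clinical = generate_cohort(CohortParams(n_patients=5000, seed=11))
    return build_profiles(filter_exonic(mutations), clinical)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
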