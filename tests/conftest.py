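import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cartpk as ck

settings.register_profile(
    "ci",
    max_examples=40,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

np.seterr(all="ignore")


@pytest.fixture(scope="session")
def ref_params() -> ck.IndividualParams:
    """Typical-subject structural parameters at the reference estimates."""
    return ck.IndividualParams(
        c_max=67060.0, t_max=8.657, foldx=5460.0, fb=0.1172, alpha=0.1093, beta=0.006122
    )


@pytest.fixture(scope="session")
def ref_pop() -> ck.PopulationModel:
    return ck.reference_population_model()


@pytest.fixture(scope="session")
def small_cohort(ref_pop) -> ck.KineticDataset:
    """An 18-subject study-like cohort (fixed seed)."""
    return ck.generate_cohort(ck.CohortConfig(seed=7), ref_pop)
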