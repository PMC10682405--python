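import numpy as np
import pandas as pd
import pytest

from otofmr.cohort import CohortSpec, generate_cohort
from otofmr.params import McConfig, ParameterSet


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def small_cohort():
    """200 fish with full (measurement + biological) noise."""
    spec = CohortSpec(n_fish=200, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort with no biological scatter and no measurement noise."""
    spec = CohortSpec(n_fish=150, seed=5, resid_sd=0.0, measurement_noise=False)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def recovery_cohort():
    """2000 fish under Table-2 measurement noise only (recovery conditions)."""
    spec = CohortSpec(n_fish=2000, seed=99, resid_sd=0.0)
    return generate_cohort(spec)


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    rng = np.random.default_rng(2)
    n = 12
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "age_group": ["age0", "yearling"] * (n // 2),
            "origin": ["west", "med"] * (n // 2),
            "capture_region": "test",
            "birth_year": 2005,
            "d13C_oto": rng.uniform(-9.5, -7.5, n),
            "d18O_oto": rng.uniform(-1.5, 0.0, n),
        }
    )


@pytest.fixture
def zero_width_params() -> ParameterSet:
    return ParameterSet().with_overrides(
        ci_a=0.0,
        ci_b=0.0,
        ci_d13C_diet=0.0,
        ci_d13C_DIC=0.0,
        ci_d18O_water=0.0,
        ci_d13C_oto=0.0,
        ci_d18O_oto=0.0,
    )


@pytest.fixture
def fast_mc() -> McConfig:
    return McConfig(n_replicates=50, seed=3)
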