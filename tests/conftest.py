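import numpy as np
import pytest

from spiroref import CohortSpec, CopdSpec, generate_copd, generate_healthy


@pytest.fixture(scope="session")
def healthy_cohort():
    """Default healthy cohort (study demographics, published residual SDs)."""
    return generate_healthy(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Healthy cohort with zero residual noise: measurements equal the
    local-equation predictions exactly."""
    from spiroref.simulate import NOISE_DEFAULTS

    return generate_healthy(
        CohortSpec(n=400, seed=3, noise={k: 0.0 for k in NOISE_DEFAULTS})
    )


@pytest.fixture(scope="session")
def copd_cohort():
    return generate_copd(CopdSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def cohort_csv(tmp_path):
    """Small well-formed cohort file on disk."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "id,sex,age_years,height_cm,weight_kg,fev1_l,fvc_l\n"
        "s1,M,40,175,80,3.5,4.4\n"
        "s2,F,55.5,162,68,2.4,3.0\n"
        "s3,m,30,180,85,4.1,5.0\n"
    )
    return path
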