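import numpy as np
import pandas as pd
import pytest

from methsubtypes.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition planted cohort (307 samples, 2000 probes,
    K = 7, 700 specific CpGs at delta 0.3), without missing entries so
    stages downstream of imputation can consume it directly."""
    return generate_cohort(CohortSpec(seed=11, missing_frac=0.0))


@pytest.fixture(scope="session")
def tiny_spec():
    """A small, fast cohort spec for smoke/round-trip tests."""
    return CohortSpec(n_samples=90, n_cpgs=300, n_subtypes=3,
                      n_specific_per_subtype=40, missing_frac=0.02,
                      n_flagged_crossreactive=5, n_sexchrom=5, n_snp=5,
                      seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_clinical():
    """Six-subject survival fixture used for hand-checkable statistics."""
    return pd.DataFrame(
        {
            "followup_days": [100.0, 200.0, 300.0, 150.0, 250.0, 400.0],
            "event": [1, 1, 0, 1, 1, 1],
            "T": [1, 2, 3, 1, 2, 4],
            "N": [0, 0, 1, 0, 1, 1],
            "M": [0, 0, 1, 0, 0, 1],
            "stage": [1, 2, 4, 1, 2, 4],
            "grade": [2, 2, 3, 1, 3, 4],
            "age_years": [55.0, 62.0, 70.0, 48.0, 66.0, 59.0],
            "sex": ["male", "female", "male", "female", "male", "female"],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )
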