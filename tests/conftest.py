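import numpy as np
import pandas as pd
import pytest

from massmva import SyntheticCohortSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_cohort():
    """Default-sized (19+25) null cohort with 4 regions."""
    spec = SyntheticCohortSpec(n_regions=4, seed=7)
    return simulate_cohort(spec)


def random_design(rng, n=20, n_confounds=2):
    """Intercept + balanced group + random confounds, as plain arrays."""
    group = np.repeat([0.0, 1.0], [n // 2, n - n // 2])
    conf = rng.standard_normal((n, n_confounds))
    X = np.column_stack([np.ones(n), group, conf])
    roles = ["intercept", "group"] + ["confound"] * n_confounds
    return X, roles


def cohort_frame(rng, n1=10, n2=12):
    """Minimal cohort metadata table without features."""
    n = n1 + n2
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "diagnosis": ["a"] * n1 + ["b"] * n2,
            "age": rng.uniform(18, 65, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "tiv": rng.normal(1450, 120, n),
        }
    )
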