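import numpy as np
import pandas as pd
import pytest

from fpmort.pipeline import analyze_stratum
from fpmort.synthetic_data import apply_inclusion, default_config, generate_cohort


@pytest.fixture(scope="session")
def included_cohort() -> pd.DataFrame:
    """One seeded default two-sex cohort (50k per stratum) after inclusion
    filtering; shared across test modules to keep the suite fast."""
    cfg = default_config(n_per_stratum=50_000, seed=3)
    cohort, _ = apply_inclusion(generate_cohort(cfg))
    return cohort


@pytest.fixture(scope="session")
def male_stratum(included_cohort):
    sub = included_cohort[included_cohort["sex"] == "male"].reset_index(drop=True)
    return analyze_stratum(sub, "male")


@pytest.fixture(scope="session")
def female_stratum(included_cohort):
    sub = included_cohort[included_cohort["sex"] == "female"].reset_index(drop=True)
    return analyze_stratum(sub, "female")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_logit_data(rng):
    """A small unit-weight logistic dataset for oracle comparisons."""
    n = 200
    X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
    eta = -0.5 + 0.8 * X[:, 0] - 0.4 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y
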