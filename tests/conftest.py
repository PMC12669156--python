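import numpy as np
import pandas as pd
import pytest

from stentrisk import CohortTable, VariableSchema, default_spec, sample_cohort


@pytest.fixture(scope="session")
def study_spec():
    return default_spec()


@pytest.fixture(scope="session")
def cohort826(study_spec):
    """Canonical synthetic cohort at the study size."""
    return sample_cohort(study_spec, 826, 20250826)


@pytest.fixture(scope="session")
def small_cohort(study_spec):
    return sample_cohort(study_spec, 300, 7)


def make_toy_table(n: int, d: int, coefs: dict[int, float], seed: int,
                   intercept: float = -0.5) -> CohortTable:
    """Gaussian-feature cohort with a sparse logistic signal in ``coefs``."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    eta = intercept + sum(c * X[:, j] for j, c in coefs.items())
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    schema = [VariableSchema(f"f{j}", "continuous_normal") for j in range(d)]
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(d)])
    return CohortTable(schema, df, y)


@pytest.fixture(scope="session")
def toy_signal_table():
    """d=6 toy with planted signal in features f1 and f3."""
    return make_toy_table(300, 6, {1: 1.6, 3: 1.3}, seed=11)
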