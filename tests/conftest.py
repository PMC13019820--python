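import numpy as np
import pandas as pd
import pytest

from psychocortex.atlas import make_parcellation
from psychocortex.cohort import MorphometryMatrix, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas360():
    return make_parcellation(360, seed=1)


@pytest.fixture(scope="session")
def atlas60():
    return make_parcellation(60, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort shared by integration-style tests."""
    cfg = SyntheticConfig(
        n_subjects={"low": 80, "moderate": 40, "high": 80}, n_parcels=60, seed=7
    )
    return generate_cohort(cfg)


def make_morphometry(values, index_kind="CT", covariates=None, names=None):
    """Helper to wrap a raw array as a MorphometryMatrix with random covariates."""
    n, p = values.shape
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id")
    if covariates is None:
        rng = np.random.default_rng(0)
        covariates = pd.DataFrame(
            {
                "age": rng.normal(34, 8, n),
                "iq": rng.normal(98, 13, n),
                "tiv": rng.normal(1.58e6, 1.5e5, n),
            },
            index=idx,
        )
    else:
        covariates = covariates.set_axis(idx)
    cols = names if names is not None else [f"p{j}" for j in range(p)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    return MorphometryMatrix(df, index_kind, covariates)
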