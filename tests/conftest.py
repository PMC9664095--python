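import numpy as np
import pandas as pd
import pytest

from stromasig import CohortConfig, generate_cohort
from stromasig.scoring import GeneSet


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def small_expr():
    """6 genes x 4 samples, distinct values, deterministic."""
    rng = np.random.default_rng(5)
    genes = ["GA", "GB", "GC", "GD", "GE", "GF"]
    samples = ["S1", "S2", "S3", "S4"]
    return pd.DataFrame(rng.normal(7, 2, size=(6, 4)), index=genes, columns=samples)


@pytest.fixture
def toy_surv():
    """6-sample survival table with events and censoring at distinct times."""
    return pd.DataFrame(
        {
            "rfs_months": [3.0, 5.0, 7.0, 11.0, 13.0, 17.0],
            "event": [1, 0, 1, 1, 0, 1],
        },
        index=[f"P{i}" for i in range(1, 7)],
    )


def make_geneset(*members, name="SET"):
    return GeneSet(name, tuple(members))
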