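import numpy as np
import pandas as pd
import pytest

from mirna_integrate import CohortConfig, generate_cohort

SMALL_CONFIG = CohortConfig(
    n_mirna=60,
    n_gene=400,
    de_mirna_frac=0.1,
    n_targets_per_mirna=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down synthetic cohort (60 assays, 400 genes) for fast unit tests."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the emulated study scale: 20+50 samples, 384 assays, 2000 genes."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_ct(values, mirnas=None, samples=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return pd.DataFrame(
        values,
        index=mirnas or [f"m{i}" for i in range(m)],
        columns=samples or [f"s{j}" for j in range(n)],
    )
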