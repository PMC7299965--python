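import numpy as np
import pandas as pd
import pytest

from dcisibc.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_per_group=5,
        n_normal=4,
        n_genes=200,
        n_cpgs=800,
        n_window_cpgs=100,
        n_meth_genes=20,
        n_diff_genes=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_expression(values, genes=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)
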