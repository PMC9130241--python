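import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from cernet import CountsMatrix, SimConfig, simulate_all, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """One full simulated study at the default stated world (seeded)."""
    return simulate_all(SimConfig(seed=123))


@pytest.fixture(scope="session")
def small_counts():
    """Small seeded count matrix with planted DE genes for fast DE tests."""
    cfg = SimConfig(n_lnc=5, n_mir=5, n_mrna=300, n_triples=5, seed=7)
    counts, truth = simulate_counts(cfg)
    return counts["mRNA"], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_counts(array, conditions=None, genes=None, samples=None) -> CountsMatrix:
    arr = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    if conditions is None:
        half = arr.shape[1] // 2
        conditions = {s: ("tumour" if i < half else "normal") for i, s in enumerate(samples)}
    return CountsMatrix(pd.DataFrame(arr, index=genes, columns=samples), conditions)
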