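import numpy as np
import pandas as pd
import pytest


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20241120)


@pytest.fixture
def random_counts(rng):
    """A seeded 50x10 fractional count matrix."""
    return make_matrix(rng.gamma(2.0, 20.0, size=(50, 10)).round(3))
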