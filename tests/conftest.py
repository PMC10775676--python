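import numpy as np
import pandas as pd
import pytest

from crosstalk.de import normalize_counts
from crosstalk.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    config = SyntheticConfig(seed=42)
    counts, samples, truth = generate_dataset(config)
    return config, counts, samples, truth


@pytest.fixture(scope="session")
def default_expression(default_dataset):
    _, counts, samples, truth = default_dataset
    return normalize_counts(counts), samples, truth


def make_de_table(log2fc, q=None, p=None, genes=None):
    """Hand-built DE result table for gate/ratio tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(log2fc)
    genes = genes or [f"g{i}" for i in range(n)]
    q = np.full(n, 1e-6) if q is None else np.asarray(q, dtype=float)
    p = q if p is None else np.asarray(p, dtype=float)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": np.sign(log2fc), "df_total": 10.0, "p": p, "q": q},
        index=pd.Index(genes, name="gene"),
    )
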