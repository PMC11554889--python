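import numpy as np
import pytest

from keygenes.datasets import ExpressionDataset


def make_dataset(values, labels, prefix="G", tag="T0"):
    """Build a minimal ExpressionDataset from a matrix and labels."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionDataset(
        gene_ids=[f"{prefix}{i}" for i in range(g)],
        sample_ids=[f"S{j}" for j in range(n)],
        values=values,
        labels=np.asarray(labels, dtype=int),
        dataset_tags=[tag] * n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 genes x 16 samples of positive noise, half cases."""
    vals = 2.0 + rng.standard_normal((20, 16))
    return make_dataset(vals, [1] * 8 + [0] * 8)
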