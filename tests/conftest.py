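import numpy as np
import pytest

from dogstat import CONTROL, EXPERIMENTAL, ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20130305)


@pytest.fixture
def tiny_dataset():
    """3 genes × 6 samples (3 control, 3 experimental); gene_2 has one outlier."""
    values = np.array(
        [
            [9.0, 10.0, 11.0, 9.5, 10.5, 10.0],
            [9.0, 10.0, 11.0, 10.0, 9.5, 15.0],
            [10.0, 10.2, 9.8, 10.1, 9.9, 10.0],
        ]
    )
    labels = [CONTROL] * 3 + [EXPERIMENTAL] * 3
    return ExpressionDataset(["gene_1", "gene_2", "gene_3"], values, labels)


def make_null_dataset(n_genes, rng, n_control=30, n_experimental=30):
    """i.i.d. N(10,1) genes — no outliers by construction."""
    values = rng.normal(10.0, 1.0, (n_genes, n_control + n_experimental))
    labels = [CONTROL] * n_control + [EXPERIMENTAL] * n_experimental
    ids = [f"null_{i}" for i in range(n_genes)]
    return ExpressionDataset(ids, values, labels)
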