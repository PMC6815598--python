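import numpy as np
import pytest

from genesieve.datasets import ExpressionDataset

# 7-gene worked example: absolute correlations, the adjacency they induce
# at threshold 0.35, and vertex weights consistent with the greedy pick
# order g1 -> g5 -> g3.
SEVEN_GENE_CORR = np.array(
    [
        [1.00, 0.59, 0.19, 0.45, 0.10, 0.24, 0.67],
        [0.59, 1.00, 0.36, 0.30, 0.11, 0.07, 0.66],
        [0.19, 0.36, 1.00, 0.31, 0.24, 0.06, 0.29],
        [0.45, 0.30, 0.31, 1.00, 0.49, 0.81, 0.12],
        [0.10, 0.11, 0.24, 0.49, 1.00, 0.72, 0.66],
        [0.24, 0.07, 0.06, 0.81, 0.72, 1.00, 0.57],
        [0.67, 0.66, 0.29, 0.12, 0.66, 0.57, 1.00],
    ]
)

SEVEN_GENE_ADJACENCY = np.array(
    [
        [0, 1, 0, 1, 0, 0, 1],
        [1, 0, 1, 0, 0, 0, 1],
        [0, 1, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 1, 1, 0],
        [0, 0, 0, 1, 0, 1, 1],
        [0, 0, 0, 1, 1, 0, 1],
        [1, 1, 0, 0, 1, 1, 0],
    ],
    dtype=bool,
)

SEVEN_GENE_WEIGHTS = np.array([1.6, 0.9, 0.5, 1.0, 1.2, 0.8, 1.1])


@pytest.fixture
def seven_gene_corr():
    return SEVEN_GENE_CORR.copy()


@pytest.fixture
def seven_gene_adjacency():
    return SEVEN_GENE_ADJACENCY.copy()


@pytest.fixture
def seven_gene_weights():
    return SEVEN_GENE_WEIGHTS.copy()


def make_dataset(matrix, labels, gene_ids=None) -> ExpressionDataset:
    matrix = np.asarray(matrix, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{j + 1}" for j in range(matrix.shape[1])]
    return ExpressionDataset(
        matrix=matrix, gene_ids=gene_ids, labels=np.asarray(labels, dtype=object)
    )


def random_dataset(rng, m=12, n=8, c=2) -> ExpressionDataset:
    """Continuous random dataset; every class gets at least 2 samples."""
    labels = np.array([f"C{k % c + 1}" for k in range(m)], dtype=object)
    return make_dataset(rng.standard_normal((m, n)), labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
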