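"""Leave-one-out 1-nearest-neighbor accuracy and the aggregate fitness.

For each held-out sample the M-1 training samples are z-scored per gene
(population mean/SD computed on the training fold only); the held-out
sample is scaled with the same statistics and classified by its
Euclidean-nearest training sample. Fitness aggregates accuracy with a
subset-size penalty:

    f(S) = w1 * CA(S) + (1 - w1) * (1 - |S| / p)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import ExpressionDataset
from .errors import ContractError

#: Training-fold SDs at or below this are replaced by 1 (gene contributes
#: its centered raw value); degenerate folds are not addressed upstream.
_SD_FLOOR = 1e-12


@dataclass(frozen=True)
class FitnessParams:
    """Weight and candidate-pool size entering the fitness function."""

    p: int
    w1: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ContractError(f"w1 must be in [0, 1], got {self.w1}")
        if self.p < 1:
            raise ContractError(f"p must be >= 1, got {self.p}")


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    n_genes: int
    fitness: float


def fitness(ca: float, n_genes: int, params: FitnessParams) -> float:
    """Aggregate accuracy and subset size into a single objective."""
    if not 0.0 <= ca <= 1.0:
        raise ContractError(f"accuracy must be in [0, 1], got {ca}")
    if not 1 <= n_genes <= params.p:
        raise ContractError(f"n_genes must be in [1, {params.p}], got {n_genes}")
    return params.w1 * ca + (1.0 - params.w1) * (1.0 - n_genes / params.p)


def loocv_accuracy_1nn(ds: ExpressionDataset, subset: Sequence[int]) -> float:
    """LOOCV accuracy of the normalization-aware 1NN on a gene subset.

    Ties in distance are broken by the lowest training-sample index.
    Note the per-fold centering cancels inside the Euclidean distance, so
    only the per-fold scale affects the prediction; the implementation
    exploits that, and running sums give each fold's moments in O(1).
    """
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size == 0:
        raise ContractError("subset must be non-empty")
    if idx.min() < 0 or idx.max() >= ds.n_genes:
        raise ContractError("gene index out of range")
    x = ds.matrix[:, idx]
    y = ds.label_codes()
    m = x.shape[0]

    tot = x.sum(axis=0)
    tot_sq = (x * x).sum(axis=0)
    correct = 0
    for i in range(m):
        mean_i = (tot - x[i]) / (m - 1)
        var_i = (tot_sq - x[i] ** 2) / (m - 1) - mean_i**2
        sd_i = np.sqrt(np.maximum(var_i, 0.0))
        sd_i[sd_i <= _SD_FLOOR] = 1.0
        diffs = (x - x[i]) / sd_i
        dists = np.einsum("ij,ij->i", diffs, diffs)
        dists[i] = np.inf
        nearest = int(np.argmin(dists))
        if y[nearest] == y[i]:
            correct += 1
    return correct / m


def evaluate_subset(
    ds: ExpressionDataset, subset: Sequence[int], params: FitnessParams
) -> EvaluationResult:
    """LOOCV accuracy plus fitness for one candidate gene subset."""
    ca = loocv_accuracy_1nn(ds, subset)
    n_genes = len(subset)
    return EvaluationResult(
        accuracy=ca, n_genes=n_genes, fitness=fitness(ca, n_genes, params)
    )
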