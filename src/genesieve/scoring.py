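"""Per-gene relevance (Fisher score) and gene-gene redundancy (|Pearson r|).

The Fisher score of gene ``i`` is

    F_i = sum_k n_k (mu_ik - mu_i)^2 / sum_k n_k sigma_ik^2

over classes ``k`` of size ``n_k``, where the class variance is the
population form (divide by ``n_k``); the class-size weighting in both the
numerator and denominator motivates that convention. Denominators are
floored at ``1e-12`` so perfectly class-constant genes get a very large
but finite score, keeping downstream selection probabilities finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset
from .errors import ContractError, ValidationError

#: Floor applied to within-class variance sums and to standard deviations.
EPS = 1e-12


@dataclass(frozen=True)
class GeneScores:
    """Fisher scores plus the per-class moments they were derived from."""

    fisher: np.ndarray  # (N,)
    class_means: np.ndarray  # (c, N)
    class_sds: np.ndarray  # (c, N)
    overall_means: np.ndarray  # (N,)
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.fisher < 0) or not np.all(np.isfinite(self.fisher)):
            raise ContractError("Fisher scores must be finite and non-negative")


@dataclass(frozen=True)
class AbsCorrelationMatrix:
    """Symmetric N x N matrix of absolute Pearson correlations in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractError("correlation matrix must be square")
        if np.any(v < 0) or np.any(v > 1):
            raise ContractError("absolute correlations must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def fisher_scores(ds: ExpressionDataset) -> GeneScores:
    """Compute class-separability scores for every gene.

    Raises
    ------
    ValidationError
        If the dataset has a single class (the score is undefined).
    """
    if ds.n_classes < 2:
        raise ValidationError("Fisher score requires at least 2 classes")
    codes = ds.label_codes()
    c = ds.n_classes
    x = ds.matrix
    counts = np.bincount(codes, minlength=c).astype(float)

    class_means = np.empty((c, ds.n_genes))
    class_vars = np.empty((c, ds.n_genes))
    for k in range(c):
        xk = x[codes == k]
        class_means[k] = xk.mean(axis=0)
        class_vars[k] = xk.var(axis=0)  # population variance
    overall = x.mean(axis=0)

    numer = (counts[:, None] * (class_means - overall) ** 2).sum(axis=0)
    denom = (counts[:, None] * class_vars).sum(axis=0)
    fisher = numer / np.maximum(denom, EPS)
    return GeneScores(
        fisher=fisher,
        class_means=class_means,
        class_sds=np.sqrt(class_vars),
        overall_means=overall,
        classes=tuple(ds.classes),
    )


def abs_correlation_matrix(
    ds: ExpressionDataset, block_size: int = 2048
) -> AbsCorrelationMatrix:
    """Absolute Pearson correlation between every pair of genes.

    Computed blockwise over gene columns so N ~ 10^4 fits in ordinary
    memory; the result is identical to the whole-matrix computation.
    Zero-variance genes get correlation 0 against everything, with the
    diagonal set to 1 uniformly.
    """
    if ds.n_samples < 3:
        raise ContractError("correlation needs at least 3 samples")
    if block_size < 1:
        raise ContractError("block_size must be positive")
    x = ds.matrix
    m, n = x.shape
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0)  # population; the 1/M factors cancel in rho
    degenerate = sd <= 0
    scale = np.where(degenerate, 1.0, sd)
    z = centered / scale

    out = np.empty((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        out[start:stop] = np.abs(z[:, start:stop].T @ z) / m
    out[degenerate, :] = 0.0
    out[:, degenerate] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    out = 0.5 * (out + out.T)  # exact symmetry against float round-off
    np.fill_diagonal(out, 1.0)
    return AbsCorrelationMatrix(values=out)
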