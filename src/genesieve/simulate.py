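"""Synthetic expression datasets with planted structure.

Three gene populations are planted in a samples-by-genes Gaussian matrix:

* *informative* genes whose class-conditional means differ (effect size
  ``delta`` expressed in units of the base noise SD),
* *redundant blocks* sharing a latent factor so that within-block pairwise
  absolute correlation is ``block_rho`` by construction,
* pure *noise* genes independent of the labels.

Informative genes discriminate along class-contrast directions spread as
evenly as possible in the (c-1)-dimensional contrast space. When more
informative genes are requested than the contrast space has dimensions,
shared class structure would make the planted genes mutually correlated
— a redundancy filter would then (correctly, but unhelpfully for
benchmarking) collapse them. To keep planted signals individually
recoverable, the generator adds cross-correlated Gaussian noise that
cancels a fraction ``decorrelation`` of the class-induced covariance
between informative genes. The price is extra within-class variance, so
the realized Fisher score of a planted gene saturates as ``delta`` grows;
the class-mean separation itself always honors ``delta * noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset
from .errors import ConfigurationError

#: Fraction of class-induced covariance between informative genes that is
#: cancelled by correlated noise (only relevant when n_informative > c - 1).
DEFAULT_DECORRELATION = 0.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Layout and effect sizes of a planted dataset."""

    M: int
    N: int
    c: int = 2
    n_informative: int = 0
    effect_size: float = 2.0
    n_blocks: int = 0
    block_size: int = 0
    block_rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    balanced: bool = True
    decorrelation: float = DEFAULT_DECORRELATION

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.M < 2 * self.c:
            raise ConfigurationError("need M >= 2c so every class has >= 2 samples")
        if self.n_informative < 0 or self.n_blocks < 0 or self.block_size < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_blocks > 0 and self.block_size < 2:
            raise ConfigurationError("blocks need at least 2 genes")
        if self.n_informative + self.n_blocks * self.block_size > self.N:
            raise ConfigurationError("planted genes exceed N")
        if not 0.0 <= self.block_rho <= 1.0:
            raise ConfigurationError("block_rho must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.decorrelation <= 1.0:
            raise ConfigurationError("decorrelation must be in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Post-shuffle column indices of each planted gene population."""

    informative: tuple[int, ...]
    blocks: tuple[tuple[int, ...], ...]
    noise: tuple[int, ...] = field(default=())


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    base = spec.M // spec.c
    sizes = np.full(spec.c, base, dtype=int)
    sizes[0] += spec.M - base * spec.c  # remainder goes to the first class
    return sizes


def _simplex_coords(proportions: np.ndarray) -> np.ndarray:
    """c class points in R^(c-1), centered and whitened under `proportions`.

    Any unit direction then has class-mean variance exactly 1, so every
    contrast direction is equally informative.
    """
    c = proportions.shape[0]
    centered = np.eye(c) - proportions[None, :]
    cov = centered.T @ np.diag(proportions) @ centered
    eigval, eigvec = np.linalg.eigh(cov)
    keep = eigval > 1e-10
    return centered @ eigvec[:, keep] / np.sqrt(eigval[keep])


def _contrast_directions(q: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit directions in R^q, spread as evenly as practical."""
    if n <= q:
        return np.eye(q)[:, :n]
    if q == 1:
        return np.ones((1, n))
    if q == 2:
        angles = np.arange(n) * np.pi / n
        return np.vstack([np.cos(angles), np.sin(angles)])
    cols = [np.eye(q)]
    while sum(b.shape[1] for b in cols) < n:
        basis, _ = np.linalg.qr(rng.standard_normal((q, q)))
        cols.append(basis)
    return np.hstack(cols)[:, :n]


def _informative_columns(
    spec: SyntheticSpec, codes: np.ndarray, proportions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class-mean matrix plus (partially decorrelated) noise, (M, n_inf)."""
    n_inf = spec.n_informative
    coords = _simplex_coords(proportions)  # (c, q)
    directions = _contrast_directions(spec.c - 1, n_inf, rng)  # (q, n_inf)
    # rms pairwise class-mean separation == effect_size * noise_sd
    scale = spec.effect_size * spec.noise_sd * np.sqrt((spec.c - 1) / (2 * spec.c))
    mu = scale * (coords @ directions)  # (c, n_inf)

    class_cov = (scale**2) * (directions.T @ directions)
    gamma = spec.decorrelation if n_inf > spec.c - 1 else 0.0
    lam_max = float(np.linalg.eigvalsh(class_cov)[-1]) if n_inf else 0.0
    base = max(
        gamma * lam_max * (1 + 1e-9),
        gamma * scale**2 + spec.noise_sd**2,
    )
    noise_cov = base * np.eye(n_inf) - gamma * class_cov
    eigval, eigvec = np.linalg.eigh(noise_cov)
    chol = eigvec * np.sqrt(np.maximum(eigval, 0.0))
    noise = rng.standard_normal((spec.M, n_inf)) @ chol.T
    return mu[codes] + noise


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw one dataset; deterministic for a fixed spec (single rng stream)."""
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    codes = np.repeat(np.arange(spec.c), sizes)
    labels = np.array([f"C{k + 1}" for k in codes], dtype=object)
    proportions = sizes / spec.M

    columns: list[np.ndarray] = []
    if spec.n_informative:
        columns.append(_informative_columns(spec, codes, proportions, rng))
    for _ in range(spec.n_blocks):
        latent = rng.standard_normal((spec.M, 1))
        eps = rng.standard_normal((spec.M, spec.block_size))
        block = spec.noise_sd * (
            np.sqrt(spec.block_rho) * latent + np.sqrt(1 - spec.block_rho) * eps
        )
        columns.append(block)
    n_noise = spec.N - spec.n_informative - spec.n_blocks * spec.block_size
    if n_noise:
        columns.append(rng.normal(0.0, spec.noise_sd, size=(spec.M, n_noise)))

    matrix = np.hstack(columns)
    order = rng.permutation(spec.N)
    position = np.empty(spec.N, dtype=int)
    position[order] = np.arange(spec.N)  # original column -> shuffled position

    informative = tuple(sorted(int(i) for i in position[: spec.n_informative]))
    blocks = []
    offset = spec.n_informative
    for _ in range(spec.n_blocks):
        blocks.append(
            tuple(sorted(int(i) for i in position[offset : offset + spec.block_size]))
        )
        offset += spec.block_size
    noise_idx = tuple(sorted(int(i) for i in position[offset:]))

    ds = ExpressionDataset(
        matrix=matrix[:, order],
        gene_ids=[f"g{j + 1}" for j in range(spec.N)],
        labels=labels,
    )
    return ds, PlantedTruth(
        informative=informative, blocks=tuple(blocks), noise=noise_idx
    )
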