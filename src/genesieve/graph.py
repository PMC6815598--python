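"""Gene-similarity graph and the greedy maximum-weight independent set.

Vertices are genes weighted by Fisher score; an edge joins two genes
whose absolute correlation strictly exceeds the threshold ``r0``. The
greedy heuristic repeatedly takes the heaviest remaining vertex and
deletes its neighborhood, yielding a maximal independent set that serves
as a "maximum relevance, minimum redundancy" candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .scoring import AbsCorrelationMatrix, GeneScores

#: Positive floor for vertex weights (weights must be strictly positive).
WEIGHT_FLOOR = 1e-12


@dataclass(frozen=True)
class SimilarityGraph:
    """0/1 symmetric adjacency with positive per-vertex weights."""

    adjacency: np.ndarray  # (N, N) bool
    weights: np.ndarray  # (N,) float, strictly positive
    r0: float

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError("adjacency must be square")
        if a.dtype != bool:
            raise ContractError("adjacency must be boolean")
        if np.any(np.diag(a)):
            raise ContractError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ContractError("adjacency must be symmetric")
        if self.weights.shape != (a.shape[0],):
            raise ContractError("one weight per vertex required")
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise ContractError("weights must be positive and finite")

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class IndependentSet:
    """Vertices selected by the greedy heuristic, in selection order."""

    members: tuple[int, ...]
    total_weight: float


def build_graph(
    corr: AbsCorrelationMatrix, scores: GeneScores, r0: float
) -> SimilarityGraph:
    """Threshold the correlation matrix into an adjacency (strict ``> r0``)."""
    if not 0.0 <= r0 <= 1.0:
        raise ContractError(f"r0 must be in [0, 1], got {r0}")
    if corr.n_genes != scores.fisher.shape[0]:
        raise ContractError("correlation matrix and scores are misaligned")
    adjacency = corr.values > r0
    np.fill_diagonal(adjacency, False)
    weights = np.maximum(scores.fisher, WEIGHT_FLOOR)
    return SimilarityGraph(adjacency=adjacency, weights=weights, r0=float(r0))


def greedy_mwis(graph: SimilarityGraph) -> IndependentSet:
    """Greedy maximum-weight independent set.

    Repeatedly select the heaviest remaining vertex (ties broken by the
    lowest index), then remove it together with its neighborhood. The
    result is always maximal and independent, and deterministic.
    """
    n = graph.n_vertices
    alive = np.ones(n, dtype=bool)
    members: list[int] = []
    weights = graph.weights
    while alive.any():
        masked = np.where(alive, weights, -np.inf)
        v = int(np.argmax(masked))  # argmax returns the lowest index on ties
        members.append(v)
        alive[v] = False
        alive[graph.adjacency[v]] = False
    total = float(weights[members].sum()) if members else 0.0
    return IndependentSet(members=tuple(members), total_weight=total)
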