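"""Roulette-wheel Add/Del refinement of a candidate gene subset.

Add draws an excluded gene with probability proportional to its Fisher
score; Del draws an included gene with probability proportional to
max(F) - F_j, so low-score genes are preferred for removal. Each flip is
evaluated and kept only on strict fitness improvement. With n_add = 0
the procedure degenerates to backward generation (deletion-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .aco import AntSolution, EvaluationCache
from .errors import ContractError


@dataclass(frozen=True)
class LsParams:
    """it_max counts consecutive iterations without an accepted move."""

    it_max: int = 5
    n_add: int = 3
    n_del: int = 5

    def __post_init__(self) -> None:
        if self.it_max < 1:
            raise ContractError("it_max must be >= 1")
        if self.n_add < 0 or self.n_del < 0:
            raise ContractError("n_add and n_del must be non-negative")
        if self.n_add + self.n_del < 1:
            raise ContractError("at least one Add or Del per iteration required")


#: Backward-generation settings: deletion-only shrink of the final subset.
BACKWARD_DEFAULTS = LsParams(it_max=20, n_add=0, n_del=2)


def add_probabilities(fisher_excluded: np.ndarray) -> np.ndarray:
    """P_i = F_i / sum(F); uniform when all scores are zero."""
    f = np.asarray(fisher_excluded, dtype=float)
    if f.size == 0:
        raise ContractError("no excluded genes to add")
    if np.any(f < 0):
        raise ContractError("Fisher scores must be non-negative")
    total = f.sum()
    if total <= 0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def del_probabilities(fisher_included: np.ndarray) -> np.ndarray:
    """P_i proportional to max(F) - F_i; uniform when all scores equal."""
    f = np.asarray(fisher_included, dtype=float)
    if f.size == 0:
        raise ContractError("no included genes to delete")
    if np.any(f < 0):
        raise ContractError("Fisher scores must be non-negative")
    fbar = f.max() - f
    total = fbar.sum()
    if total <= 0:
        return np.full(f.size, 1.0 / f.size)
    return fbar / total


def _roulette_order(
    pool: np.ndarray,
    prob_fn: Callable[[np.ndarray], np.ndarray],
    fisher: np.ndarray,
    rng: np.random.Generator,
    n_draws: int,
) -> list[int]:
    """Draw up to n_draws genes without replacement via repeated roulette."""
    chosen: list[int] = []
    remaining = list(pool)
    for _ in range(min(n_draws, len(remaining))):
        probs = prob_fn(fisher[remaining])
        pick = rng.choice(len(remaining), p=probs)
        chosen.append(remaining.pop(int(pick)))
    return chosen


def local_search(
    start: AntSolution,
    fisher: np.ndarray,
    params: LsParams,
    evaluator: EvaluationCache,
    rng: np.random.Generator,
) -> AntSolution:
    """Iterated single-flip improvement with roulette-biased proposals.

    Per iteration: up to ``n_add`` Add moves then up to ``n_del`` Del
    moves; each flip is reverted unless fitness strictly improves. A gene
    rejected once is not redrawn within the same iteration, a deletion
    that would empty the subset is skipped, and the search stops after
    ``it_max`` consecutive iterations without improvement. The returned
    solution never has lower fitness than ``start``.
    """
    if start.evaluation.n_genes < 1:
        raise ContractError("start solution must be non-empty")
    current = start
    stall = 0
    while stall < params.it_max:
        improved = False
        bits = current.bits.copy()

        for gene in _roulette_order(
            np.flatnonzero(bits == 0), add_probabilities, fisher, rng, params.n_add
        ):
            bits[gene] = 1
            candidate = AntSolution(bits=bits.copy(), evaluation=evaluator(bits))
            if candidate.fitness > current.fitness:
                current = candidate
                improved = True
            else:
                bits[gene] = 0

        for gene in _roulette_order(
            np.flatnonzero(bits == 1), del_probabilities, fisher, rng, params.n_del
        ):
            if bits.sum() <= 1:
                break  # never delete to empty
            bits[gene] = 0
            candidate = AntSolution(bits=bits.copy(), evaluation=evaluator(bits))
            if candidate.fitness > current.fitness:
                current = candidate
                improved = True
            else:
                bits[gene] = 1

        stall = 0 if improved else stall + 1
    return current
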