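"""Ant-colony wrapper over binary gene-inclusion paths.

Each ant walks the candidate genes in index order and chooses pathway 1
(select) or 0 (skip) per gene with probability

    p_ij = tau_ij^alpha * eta_ij^beta / (tau_i0^alpha eta_i0^beta + tau_i1^alpha eta_i1^beta)

where the select heuristic eta_i1 = F_i / (1 + N_s) discounts a gene's
Fisher score by the number of genes already selected on the path, and the
skip heuristic eta_i0 applies the same discount to the mean Fisher score.
Pheromones receive a local update after every ant and a global update
along the iteration-best ant's path, both with deposit

    dtau = max(0, lambda * CA(S) - |S| / p)

and are clamped to [tau_min, tau_max] throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .datasets import ExpressionDataset
from .errors import ContractError
from .evaluate import EvaluationResult, FitnessParams, evaluate_subset


@dataclass(frozen=True)
class AcoParams:
    """Colony-level knobs. Defaults are the recommended settings."""

    m: int = 30
    n_max: int = 100
    alpha: float = 1.2
    beta: float = 0.2
    rho_loc: float = 0.002
    rho_glob: float = 0.06
    lambda_: float = 1.6
    tau_init: float = 1.0
    tau_min: float = 0.05
    tau_max: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho_loc < 1:
            raise ContractError("rho_loc must be in (0, 1)")
        if not 0 < self.rho_glob < 1:
            raise ContractError("rho_glob must be in (0, 1)")
        if not 0 < self.tau_min <= self.tau_init <= self.tau_max:
            raise ContractError("need 0 < tau_min <= tau_init <= tau_max")
        if self.lambda_ < 1:
            raise ContractError("lambda_ must be >= 1")
        if self.m < 1:
            raise ContractError("m must be >= 1")
        if self.n_max < 0:
            # n_max == 0 disables the wrapper (used by pipeline ablations)
            raise ContractError("n_max must be >= 0")


@dataclass
class PheromoneState:
    """Paired trail intensities tau[i, j] for pathway j in {0, 1} of gene i."""

    tau: np.ndarray
    tau_min: float
    tau_max: float

    @classmethod
    def initial(cls, p: int, params: AcoParams) -> "PheromoneState":
        return cls(
            tau=np.full((p, 2), float(params.tau_init)),
            tau_min=params.tau_min,
            tau_max=params.tau_max,
        )

    def clamp(self) -> None:
        np.clip(self.tau, self.tau_min, self.tau_max, out=self.tau)


@dataclass(frozen=True)
class AntSolution:
    """A 0/1 inclusion vector over the p candidate genes, evaluated."""

    bits: np.ndarray
    evaluation: EvaluationResult

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    @property
    def fitness(self) -> float:
        return self.evaluation.fitness


@dataclass
class AcoTrajectory:
    """Best-so-far bookkeeping per iteration (drives run reports/plots)."""

    best_fitness: list[float] = field(default_factory=list)
    best_accuracy: list[float] = field(default_factory=list)
    best_n_genes: list[int] = field(default_factory=list)
    n_evaluations: int = 0


def heuristic_select(fisher_i: float, n_s: int) -> float:
    """Desirability of selecting gene i after n_s prior selections."""
    return fisher_i / (1 + n_s)


def heuristic_skip(mean_fisher: float, n_s: int) -> float:
    """Desirability of skipping: the mean score under the same discount."""
    return mean_fisher / (1 + n_s)


def transition_probability(
    tau_i0: float, tau_i1: float, eta_i0: float, eta_i1: float,
    alpha: float, beta: float,
) -> tuple[float, float]:
    """(p_i0, p_i1); falls back to (0.5, 0.5) when both weights vanish.

    Note 0**0 == 1, so beta == 0 reduces to pure pheromone competition.
    """
    w0 = tau_i0**alpha * eta_i0**beta
    w1 = tau_i1**alpha * eta_i1**beta
    total = w0 + w1
    if total <= 0.0 or not math.isfinite(total):
        return 0.5, 0.5
    return w0 / total, w1 / total


def delta_pheromone(evaluation: EvaluationResult, params: AcoParams, p: int) -> float:
    """Deposit earned by a solution: max(0, lambda * CA - n_genes / p)."""
    return max(0.0, params.lambda_ * evaluation.accuracy - evaluation.n_genes / p)


def construct_path(
    pher: PheromoneState,
    fisher: np.ndarray,
    params: AcoParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One ant's tour over all p genes; returns the raw bit vector.

    If the tour selects nothing, the gene with the largest select-weight
    tau_i1^alpha * eta_i1^beta is force-selected so the subset is usable.
    """
    p = fisher.shape[0]
    mean_fisher = float(fisher.mean())
    bits = np.zeros(p, dtype=np.uint8)
    n_s = 0
    draws = rng.random(p)
    for i in range(p):
        eta1 = heuristic_select(float(fisher[i]), n_s)
        eta0 = heuristic_skip(mean_fisher, n_s)
        _, p1 = transition_probability(
            pher.tau[i, 0], pher.tau[i, 1], eta0, eta1, params.alpha, params.beta
        )
        if draws[i] < p1:
            bits[i] = 1
            n_s += 1
    if n_s == 0:
        weight = pher.tau[:, 1] ** params.alpha * np.maximum(fisher, 0.0) ** params.beta
        bits[int(np.argmax(weight))] = 1
    return bits


def local_pheromone_update(
    pher: PheromoneState, ant: AntSolution, params: AcoParams
) -> None:
    """Evaporate every entry; deposit only on the pathways the ant used."""
    p = pher.tau.shape[0]
    delta = delta_pheromone(ant.evaluation, params, p)
    pher.tau *= 1.0 - params.rho_loc
    pher.tau[np.arange(p), ant.bits] += params.rho_loc * delta
    pher.clamp()


def global_pheromone_update(
    pher: PheromoneState, best_ant: AntSolution, params: AcoParams
) -> None:
    """Reinforce only the entries on the iteration-best ant's path."""
    p = pher.tau.shape[0]
    delta = delta_pheromone(best_ant.evaluation, params, p)
    rows = np.arange(p)
    pher.tau[rows, best_ant.bits] = (
        (1.0 - params.rho_glob) * pher.tau[rows, best_ant.bits]
        + params.rho_glob * delta
    )
    pher.clamp()


class EvaluationCache:
    """Memoizes subset evaluations by bit vector (ants repeat subsets)."""

    def __init__(self, ds: ExpressionDataset, params: FitnessParams) -> None:
        self._ds = ds
        self._params = params
        self._store: dict[bytes, EvaluationResult] = {}
        self.n_evaluations = 0

    def __call__(self, bits: np.ndarray) -> EvaluationResult:
        key = bits.tobytes()
        hit = self._store.get(key)
        if hit is not None:
            return hit
        result = evaluate_subset(self._ds, np.flatnonzero(bits), self._params)
        self._store[key] = result
        self.n_evaluations += 1
        return result


def _better(a: AntSolution, b: AntSolution | None) -> bool:
    """True when a beats b: higher fitness, then fewer genes (then earlier)."""
    if b is None:
        return True
    if a.fitness != b.fitness:
        return a.fitness > b.fitness
    return a.evaluation.n_genes < b.evaluation.n_genes


def run_aco(
    ds: ExpressionDataset,
    fisher: np.ndarray,
    params: AcoParams,
    fitness_params: FitnessParams,
    ls_hook: Callable[[AntSolution, EvaluationCache, np.random.Generator], AntSolution]
    | None = None,
) -> tuple[AntSolution, AcoTrajectory]:
    """Run the full colony on a candidate-gene dataset.

    Ants are processed sequentially; each ant's local update is applied
    immediately after its evaluation, so later ants see earlier trails.
    The iteration-best ant optionally passes through ``ls_hook`` before
    the global update. Deterministic for a fixed ``params.seed``.
    """
    p = ds.n_genes
    if fisher.shape != (p,):
        raise ContractError("one Fisher score per candidate gene required")
    cache = EvaluationCache(ds, fitness_params)
    pher = PheromoneState.initial(p, params)
    root = np.random.SeedSequence(params.seed)
    iter_seeds = root.spawn(max(params.n_max, 1))

    best: AntSolution | None = None
    trajectory = AcoTrajectory()
    for it in range(params.n_max):
        streams = iter_seeds[it].spawn(params.m + 1)
        iter_best: AntSolution | None = None
        for a in range(params.m):
            rng = np.random.default_rng(streams[a])
            bits = construct_path(pher, fisher, params, rng)
            ant = AntSolution(bits=bits, evaluation=cache(bits))
            local_pheromone_update(pher, ant, params)
            if _better(ant, iter_best):
                iter_best = ant
        assert iter_best is not None
        if ls_hook is not None:
            refined = ls_hook(
                iter_best, cache, np.random.default_rng(streams[params.m])
            )
            if _better(refined, iter_best):
                iter_best = refined
        global_pheromone_update(pher, iter_best, params)
        if _better(iter_best, best):
            best = iter_best
        trajectory.best_fitness.append(best.fitness)
        trajectory.best_accuracy.append(best.evaluation.accuracy)
        trajectory.best_n_genes.append(best.evaluation.n_genes)
    if best is None:  # n_max == 0: degenerate run, report the full pool
        bits = np.ones(p, dtype=np.uint8)
        best = AntSolution(bits=bits, evaluation=cache(bits))
    trajectory.n_evaluations = cache.n_evaluations
    return best, trajectory
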