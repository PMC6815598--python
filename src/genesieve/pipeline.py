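"""End-to-end orchestration: filter -> colony + local search -> backward shrink.

Stage 1 scores every gene, thresholds the absolute-correlation matrix at
``r0`` into a similarity graph, and extracts a greedy maximum-weight
independent set of p candidate genes. Stage 2 runs the ant colony on the
restricted dataset, refining each iteration-best ant with the local
search. Stage 3 applies deletion-only backward generation to the overall
best solution. Fisher scores are computed once on the full dataset and
reused as graph weights and search heuristics.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .aco import AcoParams, AntSolution, EvaluationCache, run_aco
from .datasets import ExpressionDataset
from .errors import ContractError
from .evaluate import FitnessParams, evaluate_subset
from .graph import build_graph, greedy_mwis
from .local_search import BACKWARD_DEFAULTS, LsParams, local_search
from .scoring import AbsCorrelationMatrix, GeneScores, abs_correlation_matrix, fisher_scores

DEFAULT_R0 = 0.35


@dataclass
class RunReport:
    """Everything needed to reproduce and inspect one pipeline run."""

    r0: float
    seed: int
    n_genes_total: int
    mwis_size: int
    mwis_genes: list[str]
    graph_n_vertices: int
    graph_n_edges: int
    selected_indices: list[int]  # 1-based, original gene order
    selected_genes: list[str]
    accuracy: float
    n_selected: int
    fitness: float
    trajectory_fitness: list[float]
    trajectory_accuracy: list[float]
    trajectory_n_genes: list[int]
    timings: dict[str, float]
    config: dict[str, Any] = field(default_factory=dict)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def run_pipeline(
    ds: ExpressionDataset,
    r0: float = DEFAULT_R0,
    aco_params: AcoParams | None = None,
    ls_params: LsParams | None = None,
    backward_params: LsParams | None = None,
    w1: float = 0.99,
    use_ls: bool = True,
    filter_only: bool = False,
    corr_block_size: int = 2048,
    precomputed_scores: GeneScores | None = None,
    precomputed_corr: AbsCorrelationMatrix | None = None,
) -> RunReport:
    """Run the full selection pipeline on one dataset.

    ``filter_only`` stops after the independent-set filter; ``use_ls=False``
    drops the local-search refinement (the wrapper-only ablation). The
    ``precomputed_*`` hooks inject stage-1 statistics, mainly for tests.
    """
    aco_params = aco_params or AcoParams()
    ls_params = ls_params or LsParams()
    backward_params = backward_params or BACKWARD_DEFAULTS
    if backward_params.n_add != 0:
        raise ContractError("backward generation must have n_add == 0")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    scores = precomputed_scores or fisher_scores(ds)
    corr = precomputed_corr or abs_correlation_matrix(ds, block_size=corr_block_size)
    graph = build_graph(corr, scores, r0)
    independent = greedy_mwis(graph)
    timings["filter"] = time.perf_counter() - t0

    members = sorted(independent.members)  # keep original gene order
    p = len(members)
    if p == 1:
        # Degenerate filter output: nothing for the wrapper to decide.
        final = evaluate_subset(ds, members, FitnessParams(p=1, w1=w1))
        return RunReport(
            r0=float(r0),
            seed=aco_params.seed,
            n_genes_total=ds.n_genes,
            mwis_size=1,
            mwis_genes=[ds.gene_ids[members[0]]],
            graph_n_vertices=graph.n_vertices,
            graph_n_edges=graph.n_edges,
            selected_indices=[members[0] + 1],
            selected_genes=[ds.gene_ids[members[0]]],
            accuracy=final.accuracy,
            n_selected=1,
            fitness=final.fitness,
            trajectory_fitness=[],
            trajectory_accuracy=[],
            trajectory_n_genes=[],
            timings=timings,
            config={"r0": float(r0), "w1": w1, "degenerate": True},
        )
    sub = ds.subset(members)
    sub_fisher = scores.fisher[members]
    fitness_params = FitnessParams(p=p, w1=w1)
    cache = EvaluationCache(sub, fitness_params)

    run_wrapper = not filter_only and aco_params.n_max > 0
    t0 = time.perf_counter()
    trajectory_fitness: list[float] = []
    trajectory_accuracy: list[float] = []
    trajectory_n_genes: list[int] = []
    if run_wrapper:
        ls_hook = None
        if use_ls:
            def ls_hook(ant: AntSolution, cache: EvaluationCache, rng: np.random.Generator) -> AntSolution:
                return local_search(ant, sub_fisher, ls_params, cache, rng)

        best, trajectory = run_aco(sub, sub_fisher, aco_params, fitness_params, ls_hook)
        trajectory_fitness = trajectory.best_fitness
        trajectory_accuracy = trajectory.best_accuracy
        trajectory_n_genes = trajectory.best_n_genes
    else:
        bits = np.ones(p, dtype=np.uint8)
        best = AntSolution(bits=bits, evaluation=cache(bits))
    timings["wrapper"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if run_wrapper and not filter_only:
        backward_rng = np.random.default_rng(
            np.random.SeedSequence([aco_params.seed, 0xBACC])
        )
        best = local_search(best, sub_fisher, backward_params, cache, backward_rng)
    timings["backward"] = time.perf_counter() - t0

    selected_local = np.flatnonzero(best.bits)
    selected_original = [members[i] for i in selected_local]
    final = evaluate_subset(ds, selected_original, fitness_params)

    return RunReport(
        r0=float(r0),
        seed=aco_params.seed,
        n_genes_total=ds.n_genes,
        mwis_size=p,
        mwis_genes=[ds.gene_ids[i] for i in members],
        graph_n_vertices=graph.n_vertices,
        graph_n_edges=graph.n_edges,
        selected_indices=[i + 1 for i in selected_original],
        selected_genes=[ds.gene_ids[i] for i in selected_original],
        accuracy=final.accuracy,
        n_selected=final.n_genes,
        fitness=final.fitness,
        trajectory_fitness=trajectory_fitness,
        trajectory_accuracy=trajectory_accuracy,
        trajectory_n_genes=trajectory_n_genes,
        timings=timings,
        config={
            "r0": float(r0),
            "w1": w1,
            "use_ls": use_ls,
            "filter_only": filter_only,
            "aco": asdict(aco_params),
            "ls": asdict(ls_params),
            "backward": asdict(backward_params),
        },
    )
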