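import numpy as np
import pytest

from genesieve.aco import (
    AcoParams,
    AntSolution,
    EvaluationCache,
    PheromoneState,
    construct_path,
    delta_pheromone,
    global_pheromone_update,
    heuristic_select,
    heuristic_skip,
    local_pheromone_update,
    run_aco,
    transition_probability,
)
from genesieve.errors import ContractError
from genesieve.evaluate import EvaluationResult, FitnessParams
from genesieve.simulate import SyntheticSpec, generate

from conftest import random_dataset


def make_eval(ca, n_genes, p, w1=0.99):
    return EvaluationResult(
        accuracy=ca, n_genes=n_genes,
        fitness=w1 * ca + (1 - w1) * (1 - n_genes / p),
    )


class TestHeuristics:
    def test_select_arithmetic(self):
        assert heuristic_select(2.0, 3) == pytest.approx(0.5)

    def test_select_zero_score(self):
        assert heuristic_select(0.0, 5) == 0.0

    def test_select_no_prior_selection(self):
        assert heuristic_select(1.7, 0) == pytest.approx(1.7)

    def test_skip_mean_of_ones(self):
        assert heuristic_skip(1.0, 0) == pytest.approx(1.0)

    def test_skip_discounted(self):
        assert heuristic_skip(1.0, 4) == pytest.approx(0.2)

    def test_skip_zero_scores(self):
        assert heuristic_skip(0.0, 2) == 0.0


class TestTransitionProbability:
    def test_symmetric_inputs(self):
        assert transition_probability(1.0, 1.0, 0.5, 0.5, 1.2, 0.2) == (0.5, 0.5)

    def test_beta_zero_uses_only_pheromones(self):
        p0, p1 = transition_probability(1.0, 3.0, 0.0, 99.0, 1.0, 0.0)
        assert (p0, p1) == (pytest.approx(0.25), pytest.approx(0.75))

    def test_derived_example(self):
        # tau=(1,1), eta=(1,4), alpha=1, beta=0.5 -> p1 = 2/(1+2)
        p0, p1 = transition_probability(1.0, 1.0, 1.0, 4.0, 1.0, 0.5)
        assert p1 == pytest.approx(2 / 3)
        assert p0 == pytest.approx(1 / 3)

    def test_degenerate_fallback(self):
        assert transition_probability(1.0, 1.0, 0.0, 0.0, 1.2, 0.2) == (0.5, 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_normalization(self, seed):
        rng = np.random.default_rng(seed)
        p0, p1 = transition_probability(
            rng.uniform(0.05, 1.4), rng.uniform(0.05, 1.4),
            rng.uniform(0, 3), rng.uniform(0, 3), 1.2, 0.2,
        )
        assert p0 + p1 == pytest.approx(1.0, abs=1e-12)


class TestPheromoneUpdates:
    def test_local_evaporation_only_on_unused_pathway(self):
        params = AcoParams(m=1, n_max=1, rho_loc=0.002, lambda_=1.6)
        pher = PheromoneState.initial(2, params)
        ant = AntSolution(
            bits=np.array([1, 0], dtype=np.uint8),
            evaluation=make_eval(0.0, 1, 2),  # delta = max(0, 0 - 0.5) = 0
        )
        local_pheromone_update(pher, ant, params)
        np.testing.assert_allclose(pher.tau, 0.998)

    def test_delta_example(self):
        params = AcoParams(lambda_=1.6)
        ev = make_eval(1.0, 10, 100)
        assert delta_pheromone(ev, params, 100) == pytest.approx(1.5)

    def test_delta_floored_at_zero(self):
        params = AcoParams(lambda_=1.0)
        ev = make_eval(0.1, 90, 100)
        assert delta_pheromone(ev, params, 100) == 0.0

    def test_local_deposit_on_used_pathway(self):
        params = AcoParams(rho_loc=0.002, lambda_=1.6)
        pher = PheromoneState.initial(2, params)
        ant = AntSolution(
            bits=np.array([1, 0], dtype=np.uint8),
            evaluation=make_eval(1.0, 1, 2),  # delta = 1.6 - 0.5 = 1.1
        )
        local_pheromone_update(pher, ant, params)
        assert pher.tau[0, 1] == pytest.approx(0.998 + 0.002 * 1.1)
        assert pher.tau[0, 0] == pytest.approx(0.998)
        assert pher.tau[1, 0] == pytest.approx(0.998 + 0.002 * 1.1)
        assert pher.tau[1, 1] == pytest.approx(0.998)

    def test_clamping_to_bounds(self):
        params = AcoParams(rho_loc=0.9, rho_glob=0.9, lambda_=1.6)
        pher = PheromoneState.initial(3, params)
        ant = AntSolution(
            bits=np.array([1, 1, 1], dtype=np.uint8),
            evaluation=make_eval(0.0, 3, 3),
        )
        for _ in range(50):
            local_pheromone_update(pher, ant, params)
        assert np.all(pher.tau >= params.tau_min)
        rich = AntSolution(
            bits=np.array([1, 1, 1], dtype=np.uint8),
            evaluation=make_eval(1.0, 1, 3),
        )
        pher.tau[:] = params.tau_max
        global_pheromone_update(pher, rich, params)
        assert np.all(pher.tau <= params.tau_max)

    def test_global_update_leaves_off_path_untouched(self):
        params = AcoParams(rho_glob=0.06, lambda_=1.6)
        pher = PheromoneState.initial(2, params)
        before = pher.tau.copy()
        best = AntSolution(
            bits=np.array([1, 0], dtype=np.uint8),
            evaluation=make_eval(1.0, 1, 2),
        )
        global_pheromone_update(pher, best, params)
        # unused pathways unchanged
        assert pher.tau[0, 0] == before[0, 0]
        assert pher.tau[1, 1] == before[1, 1]
        # used pathways moved toward delta = 1.6 - 0.5 = 1.1
        expected = 0.94 * 1.0 + 0.06 * 1.1
        assert pher.tau[0, 1] == pytest.approx(expected)
        assert pher.tau[1, 0] == pytest.approx(expected)


class TestConstructPath:
    def test_saturated_pheromone_forces_all_ones(self):
        params = AcoParams(alpha=20.0, beta=0.0)
        pher = PheromoneState.initial(10, params)
        pher.tau[:, 1] = params.tau_max
        pher.tau[:, 0] = params.tau_min
        rng = np.random.default_rng(0)
        bits = construct_path(pher, np.ones(10), params, rng)
        assert bits.sum() == 10

    def test_reproducible_for_fixed_seed(self):
        params = AcoParams()
        pher = PheromoneState.initial(20, params)
        fisher = np.linspace(0.1, 2.0, 20)
        b1 = construct_path(pher, fisher, params, np.random.default_rng(5))
        b2 = construct_path(pher, fisher, params, np.random.default_rng(5))
        np.testing.assert_array_equal(b1, b2)

    def test_empty_path_repaired_to_single_gene(self):
        params = AcoParams(alpha=20.0, beta=0.0)
        pher = PheromoneState.initial(1, params)
        pher.tau[:, 1] = params.tau_min
        pher.tau[:, 0] = params.tau_max
        # all-zero draw is near-certain; repair must select the only gene
        bits = construct_path(pher, np.array([1.0]), params, np.random.default_rng(0))
        assert bits.sum() == 1


class TestRunAco:
    @pytest.fixture()
    def small_problem(self):
        spec = SyntheticSpec(
            M=30, N=30, c=2, n_informative=3, effect_size=3.0, seed=11
        )
        ds, truth = generate(spec)
        from genesieve.scoring import fisher_scores

        return ds, fisher_scores(ds).fisher, truth

    def test_best_fitness_trajectory_non_decreasing(self, small_problem):
        ds, fisher, _ = small_problem
        params = AcoParams(m=5, n_max=10, seed=1)
        _, trajectory = run_aco(ds, fisher, params, FitnessParams(p=ds.n_genes))
        fit = trajectory.best_fitness
        assert len(fit) == 10
        assert all(a <= b + 1e-15 for a, b in zip(fit, fit[1:]))

    def test_deterministic_runs(self, small_problem):
        ds, fisher, _ = small_problem
        params = AcoParams(m=4, n_max=6, seed=9)
        best1, t1 = run_aco(ds, fisher, params, FitnessParams(p=ds.n_genes))
        best2, t2 = run_aco(ds, fisher, params, FitnessParams(p=ds.n_genes))
        np.testing.assert_array_equal(best1.bits, best2.bits)
        assert t1.best_fitness == t2.best_fitness

    def test_first_iteration_selection_frequency_near_half(self):
        """With beta=0 and uniform pheromones each gene is a coin flip."""
        params = AcoParams(m=200, n_max=1, beta=0.0, seed=3)
        pher = PheromoneState.initial(40, params)
        fisher = np.linspace(0.1, 3.0, 40)
        counts = np.zeros(40)
        root = np.random.SeedSequence(0)
        for stream in root.spawn(params.m):
            counts += construct_path(pher, fisher, params, np.random.default_rng(stream))
        freq = counts / params.m
        # binomial(200, 0.5): 6-sigma band ~ 0.5 +/- 0.21
        assert np.all(freq > 0.29) and np.all(freq < 0.71)

    def test_recovers_planted_genes(self, small_problem):
        ds, fisher, truth = small_problem
        params = AcoParams(m=10, n_max=15, seed=2)
        best, _ = run_aco(ds, fisher, params, FitnessParams(p=ds.n_genes))
        planted = set(truth.informative)
        assert len(planted & set(best.selected.tolist())) >= 2

    def test_mismatched_fisher_rejected(self, small_problem):
        ds, fisher, _ = small_problem
        with pytest.raises(ContractError):
            run_aco(ds, fisher[:-1], AcoParams(m=2, n_max=2), FitnessParams(p=ds.n_genes))


class TestParamValidation:
    def test_bad_rho(self):
        with pytest.raises(ContractError):
            AcoParams(rho_loc=0.0)

    def test_bad_tau_order(self):
        with pytest.raises(ContractError):
            AcoParams(tau_min=0.5, tau_init=0.4)

    def test_bad_lambda(self):
        with pytest.raises(ContractError):
            AcoParams(lambda_=0.5)

    def test_defaults_are_standard(self):
        params = AcoParams()
        assert (params.m, params.n_max) == (30, 100)
        assert (params.alpha, params.beta) == (1.2, 0.2)
        assert (params.rho_loc, params.rho_glob) == (0.002, 0.06)
        assert (params.lambda_, params.tau_init) == (1.6, 1.0)
        assert (params.tau_min, params.tau_max) == (0.05, 1.4)
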