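import numpy as np
import pytest

from aconas.aco import (
    ACOConfig,
    FitnessRecord,
    construct_individual,
    evaluate_population,
    fit_surrogate_and_weights,
    global_pheromone_update,
    local_pheromone_update,
    random_search,
    run_search,
    transition_probabilities,
    update_heuristic,
)
from aconas.errors import ConfigError
from aconas.search_space import (
    SINK,
    SOURCE,
    build_search_graph,
    encode_individual,
    build_slots,
)
from aconas.synthetic import generate_null_dataset


def _first_slot_edges(graph):
    return [(u, v) for (u, v) in graph.edges if u == SOURCE]


class TestTransitionProbabilities:
    def test_sums_to_one(self, deep_pool):
        graph = build_search_graph(deep_pool)
        _, probs = transition_probabilities(graph, SOURCE, None, 1.0, 1.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_candidate_probability_one(self, deep_pool):
        graph = build_search_graph(deep_pool)
        # epochs slot has a single value in deep_pool
        succ, probs = transition_probabilities(graph, SOURCE, None, 1.0, 1.0)
        assert len(succ) == 1 and probs[0] == 1.0

    def test_symmetry(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        _, probs = transition_probabilities(graph, SOURCE, None, 1.0, 1.0)
        assert np.allclose(probs, 0.5)

    def test_direct_evaluation_two_thirds(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        (e1, e2) = _first_slot_edges(graph)
        graph.edges[e1].xi = 2.0
        graph.edges[e2].xi = 1.0
        succ, probs = transition_probabilities(graph, SOURCE, None, 1.0, 1.0)
        lookup = dict(zip(succ, probs))
        assert lookup[e1[1]] == pytest.approx(2 / 3, abs=1e-12)
        assert lookup[e2[1]] == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_weights_uniform_fallback(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        for key in _first_slot_edges(graph):
            graph.edges[key].eta = 0.0
        _, probs = transition_probabilities(graph, SOURCE, None, 1.0, 1.0)
        assert np.allclose(probs, 0.5)


class TestPheromoneUpdates:
    def test_local_direct_evaluation(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        key = _first_slot_edges(graph)[0]
        graph.edges[key].xi = 2.0
        local_pheromone_update(graph, key, psi=0.1, xi0=1.0)
        assert graph.edges[key].xi == pytest.approx(1.9, abs=1e-12)

    def test_local_fixed_point(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        key = _first_slot_edges(graph)[0]
        local_pheromone_update(graph, key, psi=0.1, xi0=1.0)
        assert graph.edges[key].xi == pytest.approx(1.0, abs=1e-12)

    def test_local_contraction_toward_xi0(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        key = _first_slot_edges(graph)[0]
        graph.edges[key].xi = 5.0
        gaps = []
        for _ in range(20):
            local_pheromone_update(graph, key, psi=0.2, xi0=1.0)
            gaps.append(abs(graph.edges[key].xi - 1.0))
        assert all(b < a for a, b in zip(gaps, gaps[1:]))

    def test_global_direct_evaluation(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        rng = np.random.default_rng(0)
        ind = tiny_pool.random_individual(rng)
        rec = FitnessRecord(ind, encode_individual(ind, tiny_pool), 0.8)
        path = graph.path_of(ind)
        first = (path[0], path[1])
        graph.edges[first].eta = 0.5
        global_pheromone_update(graph, rec, phi=0.1)
        assert graph.edges[first].xi == pytest.approx(0.94, abs=1e-12)

    def test_global_off_path_unchanged(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        rng = np.random.default_rng(0)
        ind = tiny_pool.random_individual(rng)
        rec = FitnessRecord(ind, encode_individual(ind, tiny_pool), 0.8)
        on_path = set(zip(graph.path_of(ind)[:-1], graph.path_of(ind)[1:]))
        global_pheromone_update(graph, rec, phi=0.5)
        for key, edge in graph.edges.items():
            if key not in on_path:
                assert edge.xi == 1.0

    def test_global_phi_one_boundary(self, tiny_pool):
        graph = build_search_graph(tiny_pool, xi0=1.0)
        rng = np.random.default_rng(0)
        ind = tiny_pool.random_individual(rng)
        rec = FitnessRecord(ind, encode_individual(ind, tiny_pool), 0.8)
        path = graph.path_of(ind)
        key = (path[0], path[1])
        graph.edges[key].eta = 0.5
        global_pheromone_update(graph, rec, phi=1.0)
        assert graph.edges[key].xi == pytest.approx(0.4, abs=1e-12)

    def test_convex_combination_bound(self, tiny_pool):
        rng = np.random.default_rng(5)
        graph = build_search_graph(tiny_pool, xi0=1.0)
        key = _first_slot_edges(graph)[0]
        for _ in range(200):
            old = graph.edges[key].xi
            psi, xi0 = rng.uniform(0.01, 1.0), rng.uniform(0.01, 3.0)
            local_pheromone_update(graph, key, psi=psi, xi0=xi0)
            new = graph.edges[key].xi
            assert min(old, xi0) - 1e-12 <= new <= max(old, xi0) + 1e-12
            assert new > 0


class TestConstruction:
    def test_reproducible_walk(self, deep_pool):
        cfg = ACOConfig(seed=0)
        outs = []
        for _ in range(2):
            graph = build_search_graph(deep_pool, xi0=cfg.xi0)
            rng = np.random.default_rng(99)
            outs.append(construct_individual(graph, cfg, rng)[0])
        assert outs[0] == outs[1]

    def test_walk_decodes_validly(self, deep_pool):
        cfg = ACOConfig()
        graph = build_search_graph(deep_pool, xi0=cfg.xi0)
        rng = np.random.default_rng(1)
        for _ in range(100):
            ind, path = construct_individual(graph, cfg, rng)
            assert path[0] == SOURCE and path[-1] == SINK
            assert ind.depth in deep_pool.depth_choices

    def test_uniform_marginals(self, tiny_pool):
        cfg = ACOConfig(seed=0)
        graph = build_search_graph(tiny_pool, xi0=cfg.xi0)
        rng = np.random.default_rng(7)
        counts = {}
        n = 3000
        for _ in range(n):
            ind, _ = construct_individual(graph, cfg, rng, update_local=False)
            counts[ind.optimizer] = counts.get(ind.optimizer, 0) + 1
        # 3 sigma for Binomial(3000, 0.5)
        sigma = np.sqrt(n * 0.25)
        assert abs(counts["sgd"] - n / 2) < 3 * sigma

    def test_beta_zero_ignores_heuristic(self, tiny_pool):
        cfg = ACOConfig(beta=0.0, seed=0)
        graph = build_search_graph(tiny_pool, xi0=cfg.xi0)
        for (u, v), e in graph.edges.items():
            e.eta = 17.0 if v == (0, 0) else 0.001
        rng = np.random.default_rng(8)
        n = 2000
        count = sum(
            construct_individual(graph, cfg, rng, update_local=False)[0].epochs
            == tiny_pool.epochs_choices[0]
            for _ in range(n)
        )
        assert abs(count - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_boosted_edge_dominates(self, tiny_pool):
        cfg = ACOConfig(seed=0)
        graph = build_search_graph(tiny_pool, xi0=cfg.xi0)
        boosted = _first_slot_edges(graph)[0]
        graph.edges[boosted].xi *= 100
        rng = np.random.default_rng(9)
        n = 1000
        count = sum(
            construct_individual(graph, cfg, rng, update_local=False)[0].epochs
            == tiny_pool.epochs_choices[boosted[1][1]]
            for _ in range(n)
        )
        assert count / n > 0.95


class TestEvaluatePopulation:
    def test_cache_contract(self, tiny_pool):
        rng = np.random.default_rng(0)
        ind = tiny_pool.random_individual(rng)
        calls = []

        def fitness(p):
            calls.append(p)
            return 0.5

        records = evaluate_population(
            [ind, ind, ind], tiny_pool, None, None, 3, 0, fitness_fn=fitness
        )
        assert len(calls) == 1
        assert len(records) == 3 and all(r.f == 0.5 for r in records)

    def test_chance_level_on_null_data(self, simple_individual, deep_pool):
        from aconas.search_space import HyperparameterPool

        pool = HyperparameterPool(
            epochs_choices=[50], optimizer_choices=["adam"], lr_choices=[1e-2],
            depth_choices=[1], width_choices=[16], activation_choices=["tanh"],
            dropout_choices=[0.0],
        )
        ds = generate_null_dataset(48, 20, 4, seed=2)
        records = evaluate_population(
            [simple_individual], pool, ds.expression, ds.labels, 3, 0
        )
        assert 0.0 <= records[0].f <= 0.6  # chance is 0.25; wide stochastic bound

    def test_aborted_scores_zero(self):
        with pytest.raises(ConfigError):
            FitnessRecord(None, np.zeros(2), 0.5, aborted=True)


class TestSurrogate:
    def _records(self, pool, n=40, seed=0, fitness=None):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            ind = pool.random_individual(rng)
            enc = encode_individual(ind, pool)
            f = fitness(ind) if fitness else float(rng.random())
            out.append(FitnessRecord(ind, enc, f))
        return out

    def test_single_driver_column_dominates(self, tiny_pool):
        recs = self._records(
            tiny_pool, n=60,
            fitness=lambda p: 0.9 if p.optimizer == "adam" else 0.1,
        )
        nu, phi = fit_surrogate_and_weights(recs, trees=100, seed=0)
        slot = next(s for s in build_slots(tiny_pool) if s.name == "optimizer")
        block = phi[slot.col_start : slot.col_start + slot.n_cols]
        assert block.sum() > 0.5
        assert nu > 0.9

    def test_constant_fitness_fallback(self, tiny_pool):
        recs = self._records(tiny_pool, fitness=lambda p: 0.5)
        nu, phi = fit_surrogate_and_weights(recs, trees=100, seed=0)
        assert nu == 0.01
        assert np.allclose(phi, phi[0])

    def test_deterministic(self, tiny_pool):
        recs = self._records(tiny_pool, n=30, seed=4)
        a = fit_surrogate_and_weights(recs, trees=50, seed=1)
        b = fit_surrogate_and_weights(recs, trees=50, seed=1)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_phi_normalized(self, tiny_pool):
        recs = self._records(tiny_pool, n=30, seed=5)
        _, phi = fit_surrogate_and_weights(recs, trees=50, seed=0)
        assert phi.sum() == pytest.approx(1.0, abs=1e-9)


class TestUpdateHeuristic:
    def test_uniform_phi_equal_eta_per_slot(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        n_cols = len(encode_individual(
            tiny_pool.random_individual(np.random.default_rng(0)), tiny_pool
        ))
        update_heuristic(graph, nu=1.0, phi=np.full(n_cols, 1.0 / n_cols))
        etas = {graph.edges[key].eta for key in _first_slot_edges(graph)}
        assert len(etas) == 1

    def test_direct_evaluation(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        slots = build_slots(tiny_pool)
        opt_slot_idx = next(i for i, s in enumerate(slots) if s.name == "optimizer")
        phi = np.zeros(35)[: slots[-1].col_start + slots[-1].n_cols]
        phi = np.zeros(slots[-1].col_start + slots[-1].n_cols)
        phi[slots[opt_slot_idx].col_start] = 0.2
        update_heuristic(graph, nu=1.0, phi=phi)
        key = next(
            (u, v) for (u, v) in graph.edges if v == (opt_slot_idx, 0)
        )
        assert graph.edges[key].eta == pytest.approx(0.2, abs=1e-12)

    def test_eta_floor(self, tiny_pool):
        graph = build_search_graph(tiny_pool)
        slots = build_slots(tiny_pool)
        update_heuristic(graph, nu=1.0, phi=np.zeros(slots[-1].col_start + slots[-1].n_cols))
        assert all(e.eta >= 1e-6 for e in graph.edges.values())


class TestRunSearch:
    def _match_fitness(self, pool):
        target = None
        for ind in pool.iter_individuals():
            target = ind
            break

        def fitness(p):
            L, T = p.layers[0], target.layers[0]
            m = (
                (p.epochs == target.epochs)
                + (p.optimizer == target.optimizer)
                + (p.learning_rate == target.learning_rate)
                + (L.width == T.width)
                + (L.activation == T.activation)
                + (L.dropout == T.dropout)
            )
            return 0.3 + 0.7 * m / 6

        return fitness

    def test_best_trace_non_decreasing(self, tiny_pool):
        fitness = self._match_fitness(tiny_pool)
        cfg = ACOConfig(population_size=5, iterations=5, surrogate_trees=50, seed=1)
        result = run_search(None, None, tiny_pool, cfg, fitness_fn=fitness)
        trace = result.iteration_best
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_reproducible(self, tiny_pool):
        fitness = self._match_fitness(tiny_pool)
        cfg = ACOConfig(population_size=5, iterations=3, surrogate_trees=50, seed=2)
        a = run_search(None, None, tiny_pool, cfg, fitness_fn=fitness)
        b = run_search(None, None, tiny_pool, cfg, fitness_fn=fitness)
        assert a.best.individual == b.best.individual
        assert a.iteration_best == b.iteration_best

    def test_requires_data_without_fitness_fn(self, tiny_pool):
        with pytest.raises(ConfigError):
            run_search(None, None, tiny_pool, ACOConfig())

    def test_budget_bookkeeping(self, tiny_pool):
        fitness = self._match_fitness(tiny_pool)
        cfg = ACOConfig(population_size=4, iterations=3, surrogate_trees=50, seed=3)
        result = run_search(None, None, tiny_pool, cfg, fitness_fn=fitness)
        assert len(result.records) == 12
        assert len(result.iteration_best) == 3
        assert len(result.surrogate_scores) == 3

    def test_random_search_baseline_runs(self, tiny_pool):
        fitness = self._match_fitness(tiny_pool)
        ind, f = random_search(tiny_pool, 50, fitness, seed=0)
        assert 0.3 <= f <= 1.0 and ind is not None


class TestACOConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phi": 0.0},
            {"psi": 1.5},
            {"xi0": 0.0},
            {"population_size": 1},
            {"deposit": "bogus"},
            {"alpha": -1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ACOConfig(**kwargs)
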