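import numpy as np
import pytest

from fpe.data_io import ProteinNetwork
from fpe.fitness import rank_descending
from fpe.optimizer import (
    FPEConfig,
    Pollen,
    global_pollination,
    initialize_population,
    local_pollination,
    run_fpe,
    step,
)

from conftest import random_network


def make_instance(seed: int, n: int = 80, edge_p: float = 0.1):
    """Random network plus a random per-protein gsc map."""
    rng = np.random.default_rng(seed)
    net = random_network(rng, n, edge_p)
    gsc = {p: float(rng.uniform(0, 5)) for p in sorted(net.nodes)}
    return net, gsc


class TestInitializePopulation:
    def test_elite_is_top_q_by_degree(self):
        net, gsc = make_instance(0)
        config = FPEConfig(q=10, population_size=5, seed=1)
        state = initialize_population(net, gsc, config, np.random.default_rng(1))
        by_degree = sorted(net.nodes, key=lambda p: (-net.degree(p), p))
        assert state.population[0].members == frozenset(by_degree[:10])

    def test_beta_zero_makes_all_pollens_identical(self):
        net, gsc = make_instance(1)
        config = FPEConfig(q=10, population_size=6, beta=0.0, seed=2)
        state = initialize_population(net, gsc, config, np.random.default_rng(2))
        assert len({p.members for p in state.population}) == 1

    def test_beta_one_replaces_every_member(self):
        net, gsc = make_instance(2)
        config = FPEConfig(q=8, population_size=4, beta=1.0, seed=3)
        state = initialize_population(net, gsc, config, np.random.default_rng(3))
        elite = state.population[0].members
        for pollen in state.population[1:]:
            assert pollen.members.isdisjoint(elite) or len(net.nodes) < 16
            assert len(pollen.members) == 8

    def test_cardinality_and_validity(self):
        net, gsc = make_instance(3)
        config = FPEConfig(q=15, population_size=10, seed=4)
        state = initialize_population(net, gsc, config, np.random.default_rng(4))
        for pollen in state.population:
            assert len(pollen.members) == 15
            assert pollen.members <= net.nodes
            assert pollen.fitness == pytest.approx(sum(gsc[p] for p in pollen.members))

    def test_q_exceeding_nodes_is_hard_error(self):
        net, gsc = make_instance(4, n=10)
        config = FPEConfig(q=11, seed=0)
        with pytest.raises(ValueError):
            initialize_population(net, gsc, config, np.random.default_rng(0))


class TestGlobalPollination:
    def test_fixed_point_when_pollen_is_gbest_and_gamma_one(self):
        net, gsc = make_instance(5)
        config = FPEConfig(q=12, gbest_fraction=1.0, seed=6)
        members = frozenset(sorted(net.nodes)[:12])
        pollen = Pollen.from_members(members, gsc)
        out = global_pollination(pollen, pollen, net, gsc, config,
                                 np.random.default_rng(6))
        assert out.members == members

    def test_disjoint_from_gbest_gives_full_random_fill(self):
        net, gsc = make_instance(6, n=60)
        config = FPEConfig(q=10, seed=7)
        nodes = sorted(net.nodes)
        pollen = Pollen.from_members(nodes[:10], gsc)
        gbest = Pollen.from_members(nodes[10:20], gsc)
        out = global_pollination(pollen, gbest, net, gsc, config,
                                 np.random.default_rng(7))
        assert len(out.members) == 10
        # the kept intersection is empty, so nothing of the old pollen is guaranteed

    def test_result_always_q_distinct_members(self):
        net, gsc = make_instance(7)
        config = FPEConfig(q=9, seed=8)
        rng = np.random.default_rng(8)
        nodes = sorted(net.nodes)
        for _ in range(25):
            a = frozenset(rng.choice(nodes, size=9, replace=False).tolist())
            b = frozenset(rng.choice(nodes, size=9, replace=False).tolist())
            out = global_pollination(
                Pollen.from_members(a, gsc), Pollen.from_members(b, gsc),
                net, gsc, config, rng,
            )
            assert len(out.members) == 9
            assert out.members <= net.nodes


class TestLocalPollination:
    def test_identity_and_idempotence(self):
        net, gsc = make_instance(8)
        pollen = Pollen.from_members(sorted(net.nodes)[:5], gsc)
        once = local_pollination(pollen)
        assert once.members == pollen.members
        assert once.fitness == pollen.fitness
        assert local_pollination(once) == once


class TestStep:
    def test_p_zero_freezes_population(self):
        net, gsc = make_instance(9)
        config = FPEConfig(q=10, p=0.0, population_size=8, seed=10)
        rng = np.random.default_rng(10)
        state = initialize_population(net, gsc, config, rng)
        frozen = [p.members for p in state.population]
        for _ in range(10):
            state = step(state, net, gsc, config, rng)
        assert [p.members for p in state.population] == frozen
        assert state.gbest.fitness == max(p.fitness for p in state.population)

    def test_gbest_history_non_decreasing(self):
        net, gsc = make_instance(10)
        config = FPEConfig(q=12, p=0.5, population_size=10, iterations=30, seed=11)
        rng = np.random.default_rng(11)
        state = initialize_population(net, gsc, config, rng)
        for _ in range(30):
            state = step(state, net, gsc, config, rng)
        assert all(b >= a for a, b in zip(state.history, state.history[1:]))
        assert state.gbest.fitness == state.history[-1]

    def test_cardinality_preserved_every_iteration(self):
        net, gsc = make_instance(11)
        config = FPEConfig(q=14, p=0.6, population_size=6, seed=12)
        rng = np.random.default_rng(12)
        state = initialize_population(net, gsc, config, rng)
        for _ in range(20):
            state = step(state, net, gsc, config, rng)
            for pollen in state.population:
                assert len(pollen.members) == 14
                assert pollen.members <= net.nodes


class TestRunFpe:
    def test_identical_seed_gives_identical_ranking(self):
        net, gsc = make_instance(12)
        config = FPEConfig(q=10, iterations=40, seed=13)
        assert run_fpe(net, gsc, config).ranking == run_fpe(net, gsc, config).ranking

    def test_different_seeds_consume_independent_streams(self):
        net, gsc = make_instance(13)
        r1 = run_fpe(net, gsc, FPEConfig(q=10, iterations=40, seed=1))
        r2 = run_fpe(net, gsc, FPEConfig(q=10, iterations=40, seed=2))
        assert r1.state.gbest.fitness > 0 and r2.state.gbest.fitness > 0

    def test_zero_iterations_returns_best_initial_pollen(self):
        net, gsc = make_instance(14)
        config = FPEConfig(q=10, iterations=0, seed=15)
        result = run_fpe(net, gsc, config)
        assert frozenset(result.ranking) == result.state.gbest.members
        assert len(result.state.history) == 1

    def test_ranking_is_descending_with_id_tiebreak(self):
        net, gsc = make_instance(15)
        config = FPEConfig(q=12, iterations=30, seed=16)
        result = run_fpe(net, gsc, config)
        assert result.ranking == rank_descending(result.state.gbest.members, gsc)

    def test_recovers_planted_dominant_set(self):
        """Proteins with strictly dominant gsc form the unique optimum; in the
        fine-swap regime (gamma=(Q-1)/Q, all-global switching) the search must
        find exactly that set."""
        rng = np.random.default_rng(17)
        net = random_network(rng, 100, 0.06)
        nodes = sorted(net.nodes)
        planted = set(rng.choice(nodes, size=10, replace=False).tolist())
        gsc = {p: (10.0 + rng.uniform(0, 1) if p in planted else rng.uniform(0, 1))
               for p in nodes}
        config = FPEConfig(q=10, iterations=500, population_size=50, p=1.0,
                           beta=0.0, gbest_fraction=0.9, seed=18)
        result = run_fpe(net, gsc, config)
        assert set(result.ranking) == planted

    def test_final_fitness_at_least_best_initial(self):
        net, gsc = make_instance(16)
        config = FPEConfig(q=10, iterations=50, seed=19)
        result = run_fpe(net, gsc, config)
        assert result.gbest_fitness >= result.state.history[0]
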