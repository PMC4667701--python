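from collections import Counter
from dataclasses import replace
from math import isclose, log

import networkx as nx
import numpy as np
import pytest

from dkseries import (
    ClusteringStats,
    RewiringConfig,
    acceptance_probability,
    average_degree,
    clustering_stats,
    degree_distribution,
    joint_degree_distribution,
    l1_distance_clustering,
    randomize,
    sample_dk_random,
    swap_0k,
    swap_1k,
    swap_2k_restricted,
    target_rewire,
)
from dkseries.rewiring import _RewireState, _TargetingState

from oracles import graphs_with_degree_sequence


class TestAcceptanceProbability:
    def test_improving_moves_always_accepted(self):
        assert acceptance_probability(-0.3, 5.0) == 1.0
        assert acceptance_probability(0.0, 5.0) == 1.0

    def test_metropolis_value(self):
        assert isclose(acceptance_probability(log(2), 1.0), 0.5)

    def test_zero_temperature_limit(self):
        assert acceptance_probability(0.1, 1e6) < 1e-300

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.1, 0.0)


class TestSingleSwaps:
    def test_0k_preserves_edge_count(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        m = g.number_of_edges()
        for _ in range(200):
            swap_0k(g, rng)
            assert g.number_of_edges() == m

    def test_0k_rejected_on_complete_graph(self, rng):
        g = nx.complete_graph(4)
        assert not any(swap_0k(g, rng) for _ in range(50))

    def test_1k_on_two_disjoint_edges(self, rng):
        g = nx.Graph([("a", "b"), ("c", "d")])
        accepted = False
        for _ in range(20):
            if swap_1k(g, rng):
                accepted = True
                break
        assert accepted
        edges = {frozenset(e) for e in g.edges()}
        assert edges in (
            {frozenset("ad"), frozenset("cb")},
            {frozenset("ac"), frozenset("bd")},
        )

    def test_1k_preserves_degrees(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        before = dict(g.degree())
        for _ in range(200):
            swap_1k(g, rng)
        assert dict(g.degree()) == before

    def test_2k_preserves_joint_degrees(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=3)
        before = joint_degree_distribution(g)
        for _ in range(200):
            swap_2k_restricted(g, rng)
            assert joint_degree_distribution(g) == before


class TestRandomize:
    def test_zero_swaps_is_identity(self, fig1):
        out, log = randomize(fig1, RewiringConfig(level=0, swaps_per_edge=0))
        assert {frozenset(e) for e in out.edges()} == {
            frozenset(e) for e in fig1.edges()
        }
        assert log.attempted == 0

    def test_level0_chain_on_worked_example(self, fig1):
        out, _ = randomize(fig1, RewiringConfig(level=0, swaps_per_edge=2500, seed=4))
        assert out.number_of_edges() == 4
        assert average_degree(out) == 2.0

    def test_level1_preserves_degree_multiset(self, fig1):
        out, _ = randomize(fig1, RewiringConfig(level=1, swaps_per_edge=50, seed=1))
        assert sorted(d for _, d in out.degree()) == [1, 2, 2, 3]

    def test_inclusiveness_under_rewiring(self, medium_graph):
        # a level-d chain preserves all statistics below d as well
        out1, _ = randomize(medium_graph, RewiringConfig(level=1, seed=9))
        assert average_degree(out1) == average_degree(medium_graph)
        assert degree_distribution(out1) == degree_distribution(medium_graph)
        out2, _ = randomize(medium_graph, RewiringConfig(level=2, seed=9))
        assert degree_distribution(out2) == degree_distribution(medium_graph)
        assert joint_degree_distribution(out2) == joint_degree_distribution(
            medium_graph
        )

    def test_level2_changes_graph_but_not_jdm(self, medium_graph):
        out, log = randomize(medium_graph, RewiringConfig(level=2, seed=11))
        assert log.accepted > 0
        assert {frozenset(e) for e in out.edges()} != {
            frozenset(e) for e in medium_graph.edges()
        }
        assert joint_degree_distribution(out) == joint_degree_distribution(
            medium_graph
        )

    def test_reproducible_under_seed(self, medium_graph):
        cfg = RewiringConfig(level=1, seed=21)
        a, _ = randomize(medium_graph, cfg)
        b, _ = randomize(medium_graph, cfg)
        assert set(a.edges()) == set(b.edges())


class TestErgodicityAndUniformity:
    def test_1k_chain_visits_every_realization(self):
        # 2-regular on 6 nodes: the 6-cycles and the triangle pairs
        degseq = (2, 2, 2, 2, 2, 2)
        all_graphs = set(graphs_with_degree_sequence(6, degseq))
        assert len(all_graphs) == 70
        g = nx.cycle_graph(6)
        state = _RewireState(g)
        rng = np.random.default_rng(0)
        seen = {frozenset(frozenset((state.eu[e], state.ev[e])) for e in range(state.m))}
        for _ in range(100_000):
            if state.step_1k(rng):
                seen.add(
                    frozenset(
                        frozenset((state.eu[e], state.ev[e])) for e in range(state.m)
                    )
                )
            if len(seen) == len(all_graphs):
                break
        assert seen == all_graphs

    def test_2k_restricted_chain_visits_every_realization(self):
        # all nodes have equal degree, so the JDM admits the same 70 graphs
        all_graphs = set(graphs_with_degree_sequence(6, (2,) * 6))
        state = _RewireState(nx.cycle_graph(6), with_buckets=True)
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(100_000):
            state.step_2k(rng)
            seen.add(
                frozenset(
                    frozenset((state.eu[e], state.ev[e])) for e in range(state.m)
                )
            )
            if len(seen) == len(all_graphs):
                break
        assert seen == all_graphs

    def test_1k_visit_frequencies_roughly_uniform(self):
        # three perfect matchings on 4 nodes; sampling is known to be only
        # approximately uniform, hence the loose +/-25% band
        g = nx.Graph([(0, 1), (2, 3)])
        state = _RewireState(g)
        rng = np.random.default_rng(7)
        visits = Counter()
        for _ in range(30_000):
            state.step_1k(rng)
            visits[
                frozenset(frozenset((state.eu[e], state.ev[e])) for e in range(state.m))
            ] += 1
        assert len(visits) == 3
        for count in visits.values():
            assert abs(count / 30_000 - 1 / 3) <= 0.25 / 3


class TestTargeting:
    def test_target_equal_to_own_clustering_stops_immediately(self, medium_graph):
        cs = clustering_stats(medium_graph)
        out, log = target_rewire(medium_graph, cs, RewiringConfig(level=2.1, seed=0))
        assert log.attempted == 0
        assert log.final_H == 0.0
        assert set(out.edges()) == set(medium_graph.edges())

    def test_jdm_preserved_regardless_of_convergence(self, medium_graph):
        # an unreachable target: annealing must still preserve the JDM exactly
        target = ClusteringStats(mean_clustering=0.9)
        cfg = RewiringConfig(level=2.1, seed=3, max_stages=3, patience=2)
        out, log = target_rewire(medium_graph, target, cfg)
        assert not log.converged
        assert joint_degree_distribution(out) == joint_degree_distribution(
            medium_graph
        )

    def test_best_H_is_minimum_of_trace(self, medium_graph):
        target = ClusteringStats(
            mean_clustering=clustering_stats(medium_graph).mean_clustering + 0.03
        )
        cfg = RewiringConfig(level=2.1, seed=5, max_stages=15, patience=5)
        _, log = target_rewire(medium_graph, target, cfg)
        assert log.final_H <= min(h for _, h in log.H_trace) + 1e-12
        assert log.H_trace[-1][1] == log.final_H

    def test_incremental_triangle_bookkeeping_matches_recount(self, medium_graph):
        cs = clustering_stats(medium_graph)
        target = ClusteringStats(cs.mean_clustering + 0.05, cs.by_degree)
        state = _TargetingState(medium_graph, target, 2.5)
        rng = np.random.default_rng(2)
        for _ in range(2000):
            state.annealing_step(beta=20.0, rng=rng)
        g_now = state.to_graph()
        tri_true = nx.triangles(g_now)
        tri_state = {state.labels[i]: state.tri[i] for i in range(state.n)}
        assert tri_state == tri_true
        h_true = l1_distance_clustering(clustering_stats(g_now), target, 2.5)
        assert isclose(state.H, h_true, abs_tol=1e-9)

    def test_end_to_end_convergence_2p1(self, medium_graph):
        source = clustering_stats(medium_graph)
        g2, _ = randomize(medium_graph, RewiringConfig(level=2, seed=13))
        out, log = target_rewire(
            g2, source, RewiringConfig(level=2.1, seed=13, tolerance=0.005)
        )
        achieved = abs(
            clustering_stats(out).mean_clustering - source.mean_clustering
        )
        assert log.converged
        assert achieved <= 0.005


class TestSampling:
    def test_same_master_seed_gives_identical_samples(self, medium_graph):
        cfg = RewiringConfig(level=1, seed=42)
        a, _ = sample_dk_random(medium_graph, 1, 3, cfg)
        b, _ = sample_dk_random(medium_graph, 1, 3, cfg)
        for ga, gb in zip(a, b):
            assert set(ga.edges()) == set(gb.edges())

    def test_level1_samples_preserve_degree_distribution_exactly(self, medium_graph):
        graphs, _ = sample_dk_random(
            medium_graph, 1, 4, RewiringConfig(level=1, seed=8)
        )
        d1 = degree_distribution(medium_graph)
        assert all(degree_distribution(s) == d1 for s in graphs)

    def test_targeting_samples_have_exact_jdm(self, medium_graph):
        cfg = RewiringConfig(level=2.5, seed=77, max_stages=5, patience=3)
        graphs, logs = sample_dk_random(medium_graph, 2.5, 2, cfg)
        d2 = joint_degree_distribution(medium_graph)
        assert all(joint_degree_distribution(s) == d2 for s in graphs)
        assert len(logs) == 2

    def test_invalid_sample_count_rejected(self, medium_graph):
        with pytest.raises(ValueError):
            sample_dk_random(medium_graph, 1, 0, RewiringConfig(level=1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"level": 3},
            {"swaps_per_edge": -1},
            {"tolerance": -0.1},
            {"beta_initial": 0},
            {"beta_growth": 0.5},
            {"max_stages": 0},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RewiringConfig(**kwargs)

    def test_randomize_rejects_targeting_levels(self, fig1):
        with pytest.raises(ValueError):
            randomize(fig1, RewiringConfig(level=2.1))

    def test_target_rewire_rejects_randomizing_levels(self, fig1):
        with pytest.raises(ValueError):
            target_rewire(fig1, ClusteringStats(0.5), RewiringConfig(level=1))
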