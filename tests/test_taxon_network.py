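"""Co-occurrence network construction and its node/global indexes."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import oracles
from micronet import taxon_network as tn

from conftest import make_matrix


def net_from_sets(sample_sets):
    taxa = sorted(set().union(*sample_sets))
    pres = pd.DataFrame(
        [[t in s for t in taxa] for s in sample_sets],
        index=[f"s{i}" for i in range(len(sample_sets))],
        columns=taxa,
    )
    return tn.build_network(pres)


def net_from_edges(edges):
    G = nx.Graph()
    for (a, b), w in edges.items():
        G.add_edge(a, b, weight=w)
    return tn.CooccurrenceNetwork(G)


class TestBuildNetwork:
    def test_edge_weights_match_pair_enumeration(self):
        sets = [{"a", "b"}, {"a", "b"}, {"a", "c"}]
        net = net_from_sets(sets)
        assert net.edge_weight("a", "b") == 2
        assert net.edge_weight("a", "c") == 1
        assert not net.graph.has_edge("b", "c")

    def test_random_tables_match_exhaustive_oracle(self, rng):
        for _ in range(10):
            sets = [
                {f"g{j}" for j in range(10) if rng.random() < 0.4} or {"g0"}
                for _ in range(10)
            ]
            net = net_from_sets(sets)
            expected = oracles.cooccurrence_edges(sets)
            got = {
                tuple(sorted((a, b))): d["weight"]
                for a, b, d in net.graph.edges(data=True)
            }
            assert got == expected

    def test_lone_genus_is_isolated_node(self):
        net = net_from_sets([{"solo"}])
        assert net.nodes == ["solo"] and net.n_links == 0

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError, match="empty stratum"):
            tn.build_network(pd.DataFrame(columns=["a"]))

    def test_edge_weight_bounded_by_occurrence_counts(self, rng):
        sets = [{f"g{j}" for j in range(6) if rng.random() < 0.5} or {"g0"} for _ in range(12)]
        net = net_from_sets(sets)
        occ = {t: sum(t in s for s in sets) for t in net.nodes}
        for a, b, d in net.graph.edges(data=True):
            assert d["weight"] <= min(occ[a], occ[b])


class TestWeightedDegree:
    def test_hand_summation(self):
        net = net_from_sets([{"a", "b"}, {"a", "b"}, {"a", "c"}])
        wd = tn.weighted_degree(net)
        assert wd == {"a": 3.0, "b": 2.0, "c": 1.0}

    def test_isolated_node_zero_and_handshake(self):
        net = net_from_sets([{"a", "b"}, {"solo"}])
        wd = tn.weighted_degree(net)
        assert wd["solo"] == 0.0
        total_w = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert sum(wd.values()) == pytest.approx(2 * total_w)


class TestBetweenness:
    def test_path_complete_and_star(self):
        path = net_from_edges({("a", "b"): 1, ("b", "c"): 1})
        assert tn.betweenness(path) == {"a": 0.0, "b": 1.0, "c": 0.0}
        k4 = net_from_edges({(a, b): 1 for a, b in itertools.combinations("abcd", 2)})
        assert all(v == 0.0 for v in tn.betweenness(k4).values())
        star = net_from_edges({("hub", leaf): 1 for leaf in "abcd"})
        assert tn.betweenness(star)["hub"] == pytest.approx(6.0)  # C(4,2)

    def test_random_graphs_match_bruteforce(self, rng):
        for _ in range(5):
            nodes = list("abcdefgh")
            edges = {
                (a, b): 1
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.35
            }
            if not edges:
                continue
            net = net_from_edges(edges)
            adj = {v: set(net.graph.neighbors(v)) for v in net.graph}
            expected = oracles.betweenness_bruteforce(adj)
            got = tn.betweenness(net)
            for v in adj:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestClusteringCoefficient:
    def test_triangle_and_star(self):
        tri = net_from_edges({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})
        assert all(v == 1.0 for v in tn.clustering_coefficient(tri).values())
        star = net_from_edges({("hub", leaf): 1 for leaf in "abcd"})
        assert tn.clustering_coefficient(star)["hub"] == 0.0

    def test_chorded_square_matches_triangle_enumeration(self):
        # C4 {ab,bc,cd,da} + chord ac: triangle counting gives the chord
        # endpoints 2 closed pairs of 3 (CC=2/3), the others CC=1.
        edges = {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1, ("a", "d"): 1, ("a", "c"): 1}
        net = net_from_edges(edges)
        adj = {v: set(net.graph.neighbors(v)) for v in net.graph}
        expected = oracles.clustering_bruteforce(adj)
        got = tn.clustering_coefficient(net)
        assert got == pytest.approx(expected)
        assert got["a"] == pytest.approx(2 / 3) and got["b"] == pytest.approx(1.0)


class TestPageRank:
    def test_symmetric_cases(self):
        two = net_from_edges({("a", "b"): 5})
        assert tn.pagerank(two) == pytest.approx({"a": 0.5, "b": 0.5})
        cycle = net_from_edges({(f"n{i}", f"n{(i + 1) % 6}"): 1 for i in range(6)})
        assert all(v == pytest.approx(1 / 6) for v in tn.pagerank(cycle).values())

    def test_three_node_path_matches_linear_solve(self):
        edges = {("a", "b"): 2, ("b", "c"): 1}
        net = net_from_edges(edges)
        expected = oracles.pagerank_linear_solve(edges, net.nodes)
        got = tn.pagerank(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-8)

    def test_mass_sums_to_one_with_isolated_node(self):
        net = net_from_sets([{"a", "b"}, {"solo"}])
        pr = tn.pagerank(net)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)
        assert pr["solo"] < pr["a"]

    def test_matches_networkx_on_connected_graph(self, rng):
        edges = {
            (f"g{a}", f"g{b}"): int(rng.integers(1, 5))
            for a, b in itertools.combinations(range(7), 2)
            if rng.random() < 0.5
        }
        net = net_from_edges(edges)
        if not nx.is_connected(net.graph):
            net.graph.add_edge(*list(net.graph.nodes)[:2], weight=1)
        ref = nx.pagerank(net.graph, alpha=0.85, weight="weight", tol=1e-12)
        got = tn.pagerank(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(ref[v], abs=1e-6)


class TestCommunities:
    def test_two_cliques_recovered_and_match_bruteforce(self):
        edges = {}
        for block in ("abcd", "efgh"):
            for x, y in itertools.combinations(block, 2):
                edges[(x, y)] = 1
        edges[("a", "e")] = 1
        net = net_from_edges(edges)
        labels = tn.detect_communities(net, seed=0)
        groups = {}
        for v, l in labels.items():
            groups.setdefault(l, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [list("abcd"), list("efgh")]
        _, best = oracles.best_partition_bruteforce(edges, list("abcdefgh"))
        assert sorted(map(sorted, best)) == sorted(map(sorted, groups.values()))

    def test_single_clique_is_one_community(self):
        edges = {(a, b): 1 for a, b in itertools.combinations("abcde", 2)}
        labels = tn.detect_communities(net_from_edges(edges), seed=0)
        assert set(labels.values()) == {0}

    def test_partition_beats_trivial_partitions(self, rng):
        edges = {
            (f"g{a}", f"g{b}"): int(rng.integers(1, 4))
            for a, b in itertools.combinations(range(10), 2)
            if rng.random() < 0.3
        }
        net = net_from_edges(edges)
        labels = tn.detect_communities(net, seed=0)
        q = tn.modularity(net, labels)
        singletons = {v: i for i, v in enumerate(net.nodes)}
        lumped = {v: 0 for v in net.nodes}
        assert q >= tn.modularity(net, singletons) - 1e-12
        assert q >= tn.modularity(net, lumped) - 1e-12


class TestPowerLaw:
    def test_recovers_exponent(self):
        errs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = 1.0 + rng.pareto(1.5, 10_000)  # gamma = 2.5, xmin = 1
            errs.append(tn.fit_power_law(x).gamma - 2.5)
        assert abs(np.mean(errs)) < 0.1

    def test_degenerate_when_all_equal(self):
        fit = tn.fit_power_law([3.0] * 20)
        assert fit.degenerate

    def test_exponential_tail_fits_worse_than_power_law(self):
        rng = np.random.default_rng(0)
        ks_exp = tn.fit_power_law(rng.exponential(2.0, 5000)).ks_distance
        ks_pl = tn.fit_power_law(1.0 + rng.pareto(1.5, 5000)).ks_distance
        assert ks_pl < ks_exp


def test_metrics_invariant_under_relabeling(rng):
    edges = {
        (f"g{a}", f"g{b}"): int(rng.integers(1, 6))
        for a, b in itertools.combinations(range(8), 2)
        if rng.random() < 0.4
    }
    net = net_from_edges(edges)
    perm = {v: f"x{i}" for i, v in enumerate(rng.permutation(net.nodes))}
    relabeled = tn.CooccurrenceNetwork(nx.relabel_nodes(net.graph, perm))
    for fn in (tn.weighted_degree, tn.betweenness, tn.clustering_coefficient, tn.pagerank):
        base, new = fn(net), fn(relabeled)
        for v in net.nodes:
            assert new[perm[v]] == pytest.approx(base[v], abs=1e-9)


def test_annotate_attaches_full_metric_table(rng):
    net = net_from_edges({("a", "b"): 2, ("b", "c"): 1, ("a", "c"): 1})
    table = tn.annotate(net, seed=0)
    assert list(table.columns) == ["WD", "BNC", "CC", "PR", "community"]
    assert table["PR"].sum() == pytest.approx(1.0, abs=1e-9)
    assert net.graph.nodes["a"]["WD"] == table.at["a", "WD"]
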