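"""Network statistics and bridging against adjacency-matrix and
path-enumeration oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from persig import (bridge_frequency, bridge_seeds, bridge_tissues,
                    compare_to_random_networks, neighborhood_network,
                    network_stats, simulate_tissue_networks)
from persig.errors import DegenerateInputError, InputError
from persig.network import BridgeResult


class TestNeighborhoodNetwork:
    def test_small_neighborhood_taken_whole(self, weighted_graph):
        g = weighted_graph([("S", "A", 0.9), ("S", "B", 0.8), ("S", "C", 0.7),
                            ("A", "B", 0.5), ("D", "E", 0.9)])
        sub = neighborhood_network("S", g, k=100)
        assert set(sub.nodes) == {"S", "A", "B", "C"}
        assert sub.number_of_edges() == 4  # induced, keeps A-B

    def test_star_graph_top_two_by_confidence(self, weighted_graph):
        edges = [("S", n, c) for n, c in
                 [("A", 0.5), ("B", 0.9), ("C", 0.7), ("D", 0.95), ("E", 0.6)]]
        sub = neighborhood_network("S", weighted_graph(edges), k=2)
        assert set(sub.nodes) == {"S", "D", "B"}
        assert sub.number_of_edges() == 2

    def test_matches_sort_and_slice_oracle(self, weighted_graph):
        rng = np.random.default_rng(6)
        nodes = [f"N{i:02d}" for i in range(50)]
        edges = [(a, b, float(rng.uniform(0, 1)))
                 for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.2]
        g = weighted_graph(edges, nodes)
        seed = "N00"
        k = 10
        sub = neighborhood_network(seed, g, k=k)
        oracle = sorted(((-g[seed][n]["confidence"], n) for n in g[seed]))[:k]
        assert set(sub.nodes) == {seed} | {n for _, n in oracle}

    def test_absent_seed_rejected(self, weighted_graph):
        with pytest.raises(InputError):
            neighborhood_network("Z", weighted_graph([("A", "B", 1.0)]))


class TestNetworkStats:
    def test_triangle_statistics(self, weighted_graph):
        g = weighted_graph([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
                            ("D", "E", 1.0)])
        s = network_stats({"A", "B", "C"}, g)
        assert s.observed_edges == 3
        assert s.avg_degree == pytest.approx(2.0)
        assert s.avg_clustering == pytest.approx(1.0)

    def test_independent_set_statistics(self, weighted_graph):
        g = weighted_graph([("A", "B", 1.0), ("C", "D", 1.0)],
                           nodes=["A", "B", "C", "D", "E", "F"])
        s = network_stats({"A", "C", "E"}, g)
        assert s.observed_edges == 0
        assert s.avg_clustering == 0.0
        assert s.ppi_p == pytest.approx(1.0)

    def test_oe_ratio_unbiased_under_null(self):
        # random node sets in an ER background have mean O/E near 1
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(30, 0.3, seed=5)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "confidence")
        nodes = sorted(g.nodes)
        ratios = []
        for _ in range(200):
            pick = rng.choice(nodes, size=10, replace=False)
            ratios.append(network_stats(set(pick), g).oe_ratio)
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * se

    def test_matches_adjacency_matrix_oracle_on_small_graphs(self):
        # exhaustive check on random graphs up to 12 nodes
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            a = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
            a = a + a.T
            if a.sum() == 0:
                continue
            g = nx.from_numpy_array(a)
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(n)})
            nx.set_edge_attributes(g, 1.0, "confidence")
            subset = sorted(g.nodes)[: max(3, n // 2)]
            s = network_stats(set(subset), g)
            idx = [int(x[1:]) for x in subset]
            sub = a[np.ix_(idx, idx)]
            assert s.observed_edges == sub.sum() // 2
            deg = sub.sum(axis=1)
            tri = np.diag(np.linalg.matrix_power(sub, 3)) / 2
            local = [tri[i] / (deg[i] * (deg[i] - 1) / 2) if deg[i] >= 2 else 0.0
                     for i in range(len(idx))]
            assert s.avg_clustering == pytest.approx(np.mean(local), abs=1e-12)

    def test_degenerate_inputs(self, weighted_graph):
        g = weighted_graph([("A", "B", 1.0)])
        with pytest.raises(DegenerateInputError):
            network_stats({"A"}, g)
        with pytest.raises(InputError):
            network_stats({"A", "Z"}, g)


class TestCompareToRandomNetworks:
    @staticmethod
    def er_background(n=30, p=0.15, seed=3):
        g = nx.gnp_random_graph(n, p, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "confidence")
        return g

    def test_clique_attains_minimum_p(self, weighted_graph):
        g = self.er_background(40, 0.05, seed=8)
        clique = [f"C{i}" for i in range(8)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b, confidence=1.0)
        out = compare_to_random_networks(set(clique), g, n_rand=100, seed=1)
        assert out.loc["oe_ratio", "empirical_p"] == pytest.approx(1 / 101)

    def test_tiny_null_bottoms_out_at_one_eleventh(self):
        g = self.er_background()
        out = compare_to_random_networks(set(sorted(g.nodes)[:6]), g,
                                         n_rand=10, seed=2)
        assert (out["empirical_p"] >= 1 / 11 - 1e-12).all()

    def test_random_node_set_is_calibrated(self):
        # super-uniform empirical p for a uniformly chosen node set
        g = self.er_background(35, 0.2, seed=9)
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(10)
        pvals = []
        for i in range(200):
            pick = set(rng.choice(nodes, size=8, replace=False))
            out = compare_to_random_networks(pick, g, n_rand=39,
                                             seed=int(rng.integers(2**31)))
            pvals.append(out.loc["observed_edges", "empirical_p"])
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.25):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + tol


def brute_force_bridge(g, seed_a, seed_b, max_nodes, min_confidence):
    """Independent oracle: enumerate ALL simple paths, apply the documented
    order (length, total confidence desc, lexicographic), pool intermediates
    within the node budget, stopping at the first overflow."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        if d["confidence"] >= min_confidence:
            h.add_edge(u, v, confidence=d["confidence"])
    if seed_a not in h or seed_b not in h:
        return set(), False
    paths = list(nx.all_simple_paths(h, seed_a, seed_b))
    if not paths:
        return set(), False
    conf = lambda p: sum(h[u][v]["confidence"] for u, v in zip(p, p[1:]))
    paths.sort(key=lambda p: (len(p), -conf(p), tuple(p)))
    connectors, bridged = set(), False
    for p in paths:
        inter = set(p[1:-1])
        if len(connectors | inter) <= max_nodes - 2:
            connectors |= inter
            bridged = True
        else:
            break
    return connectors, bridged


class TestBridgeSeeds:
    def test_direct_edge_bridges_with_no_connectors(self, weighted_graph):
        g = weighted_graph([("A", "B", 0.95)])
        r = bridge_seeds("A", "B", g, min_confidence=0.9)
        assert r.bridged and r.connector_ids == set()

    def test_disconnected_seeds_not_bridged(self, weighted_graph):
        g = weighted_graph([("A", "X", 1.0), ("B", "Y", 1.0)])
        r = bridge_seeds("A", "B", g, min_confidence=0.5)
        assert not r.bridged and r.connector_ids == set()

    def test_absent_seed_is_logged_not_raised(self, weighted_graph):
        g = weighted_graph([("A", "X", 1.0)])
        r = bridge_seeds("A", "Z", g)
        assert not r.bridged

    def test_low_confidence_edges_ignored(self, weighted_graph):
        g = weighted_graph([("A", "M", 0.5), ("M", "B", 0.5),
                            ("A", "N", 0.95), ("N", "B", 0.95)])
        r = bridge_seeds("A", "B", g, min_confidence=0.9)
        assert r.connector_ids == {"N"}

    def test_matches_exhaustive_path_enumeration(self, weighted_graph):
        # 12-node toy graphs vs the brute-force oracle
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            nodes = [f"N{i:02d}" for i in range(10)] + ["A", "B"]
            edges = [(u, v, float(np.round(rng.uniform(0.3, 1.0), 3)))
                     for u, v in itertools.combinations(nodes, 2)
                     if rng.random() < 0.25]
            g = weighted_graph(edges, nodes)
            r = bridge_seeds("A", "B", g, max_nodes=20, min_confidence=0.5,
                             max_paths=10**6)
            oracle_conn, oracle_bridged = brute_force_bridge(
                g, "A", "B", max_nodes=20, min_confidence=0.5)
            assert r.bridged == oracle_bridged
            assert r.connector_ids == oracle_conn

    def test_invariant_to_node_relabeling(self, weighted_graph):
        edges = [("A", "M1", 0.8), ("M1", "B", 0.8),
                 ("A", "M2", 0.9), ("M2", "B", 0.7),
                 ("A", "X", 0.9), ("X", "Y", 0.9), ("Y", "B", 0.9)]
        g = weighted_graph(edges)
        r1 = bridge_seeds("A", "B", g, max_nodes=5, min_confidence=0.5)
        # relabel intermediates preserving lexicographic order
        mapping = {"M1": "Q1", "M2": "Q2", "X": "X", "Y": "Y"}
        g2 = nx.relabel_nodes(g, mapping)
        r2 = bridge_seeds("A", "B", g2, max_nodes=5, min_confidence=0.5)
        assert {mapping.get(c, c) for c in r1.connector_ids} == r2.connector_ids

    def test_budget_excludes_infeasible_first_path(self, weighted_graph):
        g = weighted_graph([("A", "X", 1.0), ("X", "Y", 1.0), ("Y", "B", 1.0)])
        r = bridge_seeds("A", "B", g, max_nodes=3, min_confidence=0.5)
        assert not r.bridged


class TestBridgeFrequency:
    def test_single_recurrent_connector_has_zero_sd(self):
        results = [BridgeResult(f"t{i}", {"X"}, 1, True) for i in range(142)]
        table = bridge_frequency(results)
        assert table.counts == {"X": 142}
        assert table.sd == 0.0
        assert table.selected == set()  # nothing exceeds mean + 2*0

    def test_uniform_counts_select_nothing(self):
        results = [BridgeResult(f"t{i}", {f"C{i % 5}"}, 1, True)
                   for i in range(20)]
        table = bridge_frequency(results)
        assert set(table.counts.values()) == {4}
        assert table.selected == set()

    def test_count_mass_balance(self):
        rng = np.random.default_rng(11)
        pool = [f"C{i}" for i in range(12)]
        results = [BridgeResult(f"t{i}",
                                set(rng.choice(pool, size=rng.integers(1, 5),
                                               replace=False)),
                                0, True) for i in range(30)]
        for r in results:
            r.n_connectors = len(r.connector_ids)
        table = bridge_frequency(results)
        assert sum(table.counts.values()) == sum(r.n_connectors for r in results)
        assert all(1 <= c <= table.n_tissues for c in table.counts.values())

    def test_selection_monotone_in_sd_multiplier(self):
        rng = np.random.default_rng(12)
        pool = [f"C{i}" for i in range(30)]
        results = [BridgeResult(f"t{i}",
                                set(rng.choice(pool, size=3, replace=False)),
                                3, True) for i in range(50)]
        table = bridge_frequency(results)
        sizes = [len(table.selected_at(k)) for k in (0.0, 1.0, 2.0, 3.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_bridged_tissue_rejected(self):
        with pytest.raises(InputError):
            bridge_frequency([BridgeResult("t1", set(), 0, False)])

    def test_planted_bridges_dominate_census(self):
        # planted high-frequency connectors survive mean+2SD selection
        uni = [f"N{i:03d}" for i in range(78)] + ["MDC1", "PHB"]
        planted = ["N001", "N002"]
        graphs = simulate_tissue_networks(uni, n_tissues=60,
                                          planted_bridges=planted,
                                          bridge_tissue_fraction=0.5,
                                          edge_density=0.04, seed=21)
        results = bridge_tissues("MDC1", "PHB", graphs, min_confidence=0.5)
        table = bridge_frequency(results)
        assert set(planted) <= table.selected
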