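"""Betweenness centrality, ranking, component census, metric correlations."""

import itertools
import random

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprior.network_builder import PPINetwork
from netprior import topology


def as_net(G):
    return PPINetwork(graph=nx.relabel_nodes(G, {v: f"N{v:03d}" for v in G}))


def bc_of(table):
    return dict(zip(table["symbol"], table["betweenness"]))


def brute_force_betweenness(G):
    """All-geodesics enumeration oracle, endpoint-excluding, normalized."""
    nodes = sorted(G)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for j, k in itertools.combinations(nodes, 2):
        if not nx.has_path(G, j, k):
            continue
        paths = list(nx.all_shortest_paths(G, j, k))
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: b / norm for v, b in bc.items()}


def union_find_sizes(G):
    parent = {v: v for v in G}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in G.edges:
        parent[find(a)] = find(b)
    from collections import Counter

    return sorted(Counter(find(v) for v in G).values(), reverse=True)


class TestBetweenness:
    def test_path_graph_center_carries_all_geodesics(self):
        table = topology.betweenness(as_net(nx.path_graph(3)))
        assert bc_of(table) == {"N000": 0.0, "N001": 1.0, "N002": 0.0}

    def test_star_center_one_leaves_zero(self):
        table = topology.betweenness(as_net(nx.star_graph(4)))
        values = bc_of(table)
        assert values["N000"] == 1.0
        assert all(values[f"N{i:03d}"] == 0.0 for i in range(1, 5))

    def test_four_cycle_every_node_one_sixth(self):
        table = topology.betweenness(as_net(nx.cycle_graph(4)))
        assert np.allclose(table["betweenness"], 1 / 6)

    def test_complete_graph_all_zero(self):
        table = topology.betweenness(as_net(nx.complete_graph(6)))
        assert (table["betweenness"] == 0).all()

    def test_tree_leaves_zero_internals_positive(self):
        table = topology.betweenness(as_net(nx.random_labeled_tree(25, seed=3)))
        net_degrees = dict(zip(table["symbol"], table["degree"]))
        for _, row in table.iterrows():
            if net_degrees[row["symbol"]] == 1:
                assert row["betweenness"] == 0.0
            else:
                assert row["betweenness"] > 0.0

    def test_path_graph_center_is_maximal(self):
        table = topology.betweenness(as_net(nx.path_graph(9)))
        assert table.loc[table["betweenness"].idxmax(), "symbol"] == "N004"

    @pytest.mark.parametrize("n,p", [(10, 0.3), (25, 0.15), (40, 0.1), (60, 0.08)])
    def test_agrees_with_brute_force_enumeration(self, n, p):
        G = nx.gnp_random_graph(n, p, seed=n)
        G = nx.relabel_nodes(G, {v: f"N{v:03d}" for v in G})
        table = topology.betweenness(PPINetwork(graph=G))
        oracle = brute_force_betweenness(G)
        got = bc_of(table)
        assert all(abs(got[v] - oracle[v]) < 1e-9 for v in G)

    def test_disconnected_graph_and_library_cross_check(self):
        G = nx.gnp_random_graph(120, 0.02, seed=7)  # typically disconnected
        G = nx.relabel_nodes(G, {v: f"N{v:03d}" for v in G})
        assert not nx.is_connected(G)
        table = topology.betweenness(PPINetwork(graph=G))
        ref_bc = nx.betweenness_centrality(G, normalized=True)
        ref_clo = nx.closeness_centrality(G)
        got = bc_of(table)
        clo = dict(zip(table["symbol"], table["closeness"]))
        assert all(abs(got[v] - ref_bc[v]) < 1e-12 for v in G)
        assert all(abs(clo[v] - ref_clo[v]) < 1e-12 for v in G)

    def test_tiny_graphs_report_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="netprior.topology"):
            table = topology.betweenness(as_net(nx.path_graph(2)))
        assert (table["betweenness"] == 0).all()
        assert any("N < 3" in r.message for r in caplog.records)


class TestRelativeBetweenness:
    def test_against_reference_maximum(self):
        table = pd.DataFrame({"symbol": ["APP"], "betweenness": [0.0240]})
        out = topology.relative_betweenness(table, reference_max=0.0441)
        assert out["relative_betweenness"].iloc[0] == 54.42

    def test_table_maximum_scores_100(self):
        table = pd.DataFrame({"symbol": ["A", "B"], "betweenness": [0.5, 0.25]})
        out = topology.relative_betweenness(table)
        assert list(out["relative_betweenness"]) == [100.0, 50.0]

    def test_all_zero_is_error(self):
        table = pd.DataFrame({"symbol": ["A"], "betweenness": [0.0]})
        with pytest.raises(ValueError, match="no central node"):
            topology.relative_betweenness(table)


class TestRanking:
    def test_ties_broken_lexicographically(self):
        table = pd.DataFrame({"symbol": ["A", "B", "C"], "betweenness": [0.5, 0.9, 0.5]})
        out = topology.rank_by_betweenness(table)
        assert list(out["symbol"]) == ["B", "A", "C"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_all_equal_gives_alphabetical_order(self):
        table = pd.DataFrame({"symbol": ["C", "A", "B"], "betweenness": [0.1] * 3})
        assert list(topology.rank_by_betweenness(table)["symbol"]) == ["A", "B", "C"]

    def test_agrees_with_independent_sort(self):
        rng = np.random.default_rng(5)
        symbols = [f"N{i:03d}" for i in range(50)]
        values = rng.choice([0.0, 0.1, 0.2, 0.3], size=50)  # force ties
        table = pd.DataFrame({"symbol": symbols, "betweenness": values})
        out = topology.rank_by_betweenness(table)
        oracle = sorted(zip(symbols, values), key=lambda t: (-t[1], t[0]))
        assert list(out["symbol"]) == [s for s, _ in oracle]


class TestComponentCensus:
    def test_published_style_census_sums_to_node_count(self):
        census = topology.ComponentCensus(sizes=[187, 6] + [3] * 9 + [2] * 13 + [1] * 210)
        assert census.total == 456
        assert census.n_singletons == 210
        assert census.n_pairs == 13
        assert census.n_triples == 9
        assert census.other_components == [187, 6]

    def test_single_edge_graph_is_one_pair(self):
        net = as_net(nx.path_graph(2))
        assert topology.component_census(net).n_pairs == 1

    @pytest.mark.parametrize("n,p", [(30, 0.03), (100, 0.015)])
    def test_matches_union_find_oracle(self, n, p):
        rng = random.Random(n)
        for _ in range(5):
            G = nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
            census = topology.component_census(PPINetwork(graph=G))
            assert census.sizes == union_find_sizes(G)
            assert census.total == n


class TestConnectedFraction:
    def test_published_counts_give_80_5(self):
        census = topology.ComponentCensus(sizes=[875] + [2] * 4 + [1] * 214)
        assert census.total == 1097
        assert topology.connected_fraction(census) == 80.5

    def test_all_connected_is_100(self):
        assert topology.connected_fraction(topology.ComponentCensus(sizes=[5])) == 100.0


class TestMetricCorrelations:
    def test_identical_metrics_correlate_perfectly(self):
        table = pd.DataFrame(
            {
                "symbol": list("ABCD"),
                "betweenness": [0.1, 0.2, 0.3, 0.4],
                "degree": [1, 2, 3, 4],
                "closeness": [0.1, 0.2, 0.3, 0.4],
            }
        )
        out = topology.metric_correlations(table)
        assert out.loc["betweenness", "degree"] == pytest.approx(1.0)
        assert np.allclose(np.diag(out), 1.0)

    def test_star_graph_center_dominates_both(self):
        table = topology.betweenness(as_net(nx.star_graph(6)))
        out = topology.metric_correlations(table)
        assert out.loc["betweenness", "degree"] > 0

    def test_constant_metric_reported_missing(self):
        table = topology.betweenness(as_net(nx.complete_graph(5)))  # betweenness all 0
        out = topology.metric_correlations(table)
        assert np.isnan(out.loc["betweenness", "degree"])

    def test_matches_rank_correlation_oracle(self):
        G = nx.gnp_random_graph(50, 0.1, seed=2)
        table = topology.betweenness(as_net(G))
        out = topology.metric_correlations(table)
        ranks = table[["betweenness", "degree", "closeness"]].rank()
        oracle = np.corrcoef(ranks.to_numpy().T)  # Pearson of ranks == Spearman
        assert np.allclose(out.to_numpy(), oracle, atol=1e-12)
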