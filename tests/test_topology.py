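import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hubnet.topology import (
    degree_distribution,
    fit_power_law,
    global_stats,
    node_centralities,
)

from conftest import relabeled, random_simple_graph
from oracles import brute_force_centralities, brute_force_cpl


class TestGlobalStats:
    def test_star_is_maximally_centralized(self):
        r = global_stats(relabeled(nx.star_graph(5)))
        assert r.centralization == pytest.approx(1.0)

    def test_triangle_panel(self):
        r = global_stats(relabeled(nx.complete_graph(3)))
        assert r.density == pytest.approx(1.0)
        assert r.clustering_coefficient == pytest.approx(1.0)
        assert r.heterogeneity == pytest.approx(0.0)
        assert r.characteristic_path_length == pytest.approx(1.0)

    def test_star_heterogeneity_closed_form(self, star_1_3):
        # degrees {3,1,1,1}: mean 1.5, population variance 0.75
        r = global_stats(star_1_3)
        assert r.heterogeneity == pytest.approx(math.sqrt(0.75) / 1.5)

    def test_path_cpl(self, path_abc):
        assert global_stats(path_abc).characteristic_path_length == (
            pytest.approx(4 / 3)
        )

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_complete_graph_cpl_is_one(self, n):
        r = global_stats(relabeled(nx.complete_graph(n)))
        assert r.characteristic_path_length == pytest.approx(1.0)

    @pytest.mark.parametrize("make", [nx.complete_graph,
                                      lambda n: nx.cycle_graph(n)])
    def test_regular_graphs_have_zero_centralization(self, make):
        r = global_stats(relabeled(make(6)))
        assert r.centralization == pytest.approx(0.0)
        assert r.heterogeneity == pytest.approx(0.0)

    def test_centralization_undefined_below_three_nodes(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        assert global_stats(g).centralization is None

    def test_disconnected_pairs_excluded_from_cpl(self):
        g = nx.Graph()
        nx.add_path(g, ["A", "B", "C"])
        g.add_edge("X", "Y")
        r = global_stats(g)
        assert r.characteristic_path_length == pytest.approx(
            brute_force_cpl(g)
        )
        # 3-path pairs (6 ordered) + edge pairs (2 ordered) of 20 total
        assert r.connected_pair_fraction == pytest.approx(8 / 20)

    def test_avg_neighbors_identity(self):
        g = random_simple_graph(30, 60, seed=3)
        r = global_stats(g)
        assert r.avg_neighbors == pytest.approx(
            2 * r.n_edges / r.n_nodes
        )

    def test_heterogeneity_isomorphism_invariant(self):
        g = random_simple_graph(20, 40, seed=9)
        h = nx.relabel_nodes(g, {v: f"Z{v}" for v in g.nodes()})
        assert global_stats(g).heterogeneity == pytest.approx(
            global_stats(h).heterogeneity
        )


class TestNodeCentralities:
    def test_star_center(self, star_1_3):
        ct = node_centralities(star_1_3)
        assert ct.loc["C", "betweenness"] == pytest.approx(1.0)
        assert ct.loc["C", "closeness"] == pytest.approx(1.0)
        assert ct.loc["C", "stress"] == 3

    def test_path_interior(self, path_abc):
        ct = node_centralities(path_abc)
        assert ct.loc["B", "stress"] == 1
        assert ct.loc["B", "betweenness"] == pytest.approx(1.0)

    def test_leaves_are_never_interior(self, star_1_3):
        ct = node_centralities(star_1_3)
        for leaf in ["L1", "L2", "L3"]:
            assert ct.loc[leaf, "betweenness"] == 0.0
            assert ct.loc[leaf, "stress"] == 0

    def test_measure_subset_selects_columns(self, path_abc):
        ct = node_centralities(path_abc, measures=("degree", "betweenness"))
        assert list(ct.columns) == ["degree", "betweenness"]

    def test_unknown_measure_rejected(self, path_abc):
        with pytest.raises(ValueError, match="unknown"):
            node_centralities(path_abc, measures=("degree", "pagerank"))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_graphs(self, seed):
        g = random_simple_graph(18, 35, seed=seed)
        ct = node_centralities(g)
        bet, clo, stress = brute_force_centralities(g)
        for v in g.nodes():
            assert ct.loc[v, "stress"] == stress[v]
            assert ct.loc[v, "betweenness"] == pytest.approx(
                bet[v], abs=1e-9)
            assert ct.loc[v, "closeness"] == pytest.approx(
                clo[v], abs=1e-9)


class TestDegreeDistribution:
    @pytest.mark.parametrize(
        "graph, expected",
        [
            (nx.complete_graph(3), [(2, 3)]),
            (nx.star_graph(3), [(1, 3), (3, 1)]),
        ],
    )
    def test_small_graphs(self, graph, expected):
        dist = degree_distribution(relabeled(graph))
        assert list(map(tuple, dist.to_numpy())) == expected

    def test_isolated_node_counts_at_degree_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("LONE")
        dist = degree_distribution(g)
        assert list(map(tuple, dist.to_numpy())) == [(0, 1), (1, 2)]
        assert dist["count"].sum() == g.number_of_nodes()


class TestPowerLawFit:
    def test_exactly_collinear_log_points(self):
        dist = pd.DataFrame(
            {"degree": [1, 2, 4, 8], "count": [64, 16, 4, 1]}
        )
        fit = fit_power_law(dist)
        assert fit.exponent == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_regular_graph_insufficient_support(self):
        dist = degree_distribution(relabeled(nx.cycle_graph(8)))
        with pytest.raises(ValueError, match="insufficient support"):
            fit_power_law(dist)

    def test_preferential_attachment_is_scale_free(self):
        from hubnet.synth import generate_interactome

        g = generate_interactome(2000, 2, random_seed=1)
        fit = fit_power_law(degree_distribution(g))
        assert fit.exponent < -1.0
        assert fit.r_squared > 0.8

    def test_degree_zero_excluded_from_support(self):
        dist = pd.DataFrame({"degree": [0, 1, 2, 4], "count": [5, 8, 4, 2]})
        assert 0 not in fit_power_law(dist).support
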