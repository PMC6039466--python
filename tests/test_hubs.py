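import networkx as nx
import pytest

from hubnet.hubs import extract_hub_subnetwork, select_hubs
from hubnet.topology import node_centralities

from conftest import relabeled, random_simple_graph


class TestSelectHubs:
    @pytest.mark.parametrize(
        "strategy", ["degree_betweenness_borda", "degree_topk", "sd_threshold"]
    )
    def test_star_center_always_wins(self, strategy):
        g = relabeled(nx.star_graph(5))
        ct = node_centralities(g)
        res = select_hubs(ct, n_hubs=1, strategy=strategy, k_sd=1.0)
        assert res.hubs[0] == "N0"

    def test_fused_star_centers_dominate(self, fused_stars):
        ct = node_centralities(fused_stars)
        res = select_hubs(ct, n_hubs=2)
        assert set(res.hubs) == {"X", "Y"}

    def test_regular_ring_sd_threshold_selects_nothing(self, caplog):
        g = relabeled(nx.cycle_graph(8))
        ct = node_centralities(g)
        with caplog.at_level("WARNING"):
            res = select_hubs(ct, strategy="sd_threshold", k_sd=2.0)
        assert res.hubs == []
        assert "no hubs" in caplog.text

    def test_n_hubs_exceeding_nodes_errors(self, path_abc):
        ct = node_centralities(path_abc)
        with pytest.raises(ValueError, match="exceeds"):
            select_hubs(ct, n_hubs=10)

    def test_borda_scale_invariance(self):
        g = random_simple_graph(25, 60, seed=4)
        ct = node_centralities(g)
        scaled = ct.copy()
        scaled["betweenness"] = scaled["betweenness"] * 17.5
        assert (
            select_hubs(ct, n_hubs=5).hubs
            == select_hubs(scaled, n_hubs=5).hubs
        )

    def test_ranking_is_total_and_deterministic(self):
        g = random_simple_graph(20, 40, seed=7)
        ct = node_centralities(g)
        r1 = select_hubs(ct, n_hubs=3).ranking
        r2 = select_hubs(ct.sample(frac=1, random_state=0), n_hubs=3).ranking
        assert list(r1.index) == list(r2.index)
        assert len(r1) == len(ct)

    def test_strategy_recorded_in_result(self, fused_stars):
        ct = node_centralities(fused_stars)
        res = select_hubs(ct, n_hubs=2, strategy="degree_topk")
        assert res.strategy == "degree_topk"
        assert res.parameters["n_hubs"] == 2


class TestExtractHubSubnetwork:
    def test_unique_geodesic_path(self):
        g = nx.Graph()
        nx.add_path(g, ["A", "B", "C", "D", "E"])
        sub = extract_hub_subnetwork(g, ["A", "E"], "geodesic_union")
        assert set(sub.graph.nodes()) == {"A", "B", "C", "D", "E"}
        assert sub.graph.number_of_edges() == 4

    def test_tied_geodesics_all_kept(self):
        g = relabeled(nx.cycle_graph(4), "")  # nodes "0".."3"
        sub = extract_hub_subnetwork(g, ["0", "2"], "geodesic_union")
        assert set(sub.graph.nodes()) == {"0", "1", "2", "3"}
        assert sub.graph.number_of_edges() == 4

    def test_induced_on_adjacent_hubs(self, path_abc):
        sub = extract_hub_subnetwork(path_abc, ["A", "B"], "induced")
        assert set(sub.graph.nodes()) == {"A", "B"}
        assert sub.graph.number_of_edges() == 1

    def test_neighbors_strategy_superset_of_induced(self, fused_stars):
        hubs = ["X", "Y"]
        ind = extract_hub_subnetwork(fused_stars, hubs, "induced")
        nbr = extract_hub_subnetwork(fused_stars, hubs, "neighbors")
        assert set(ind.graph.nodes()) <= set(nbr.graph.nodes())
        assert set(nbr.graph.nodes()) == set(fused_stars.nodes())

    def test_absent_hub_named_in_error(self, path_abc):
        with pytest.raises(ValueError, match="ZZZ"):
            extract_hub_subnetwork(path_abc, ["A", "ZZZ"], "induced")

    @pytest.mark.parametrize("seed", range(4))
    def test_geodesic_union_invariants(self, seed):
        g = random_simple_graph(20, 45, seed=seed)
        nodes = sorted(g.nodes())
        hubs = nodes[:4]
        sub = extract_hub_subnetwork(g, hubs, "geodesic_union")
        assert set(hubs) <= set(sub.graph.nodes())
        # every non-hub node lies on >= 1 hub-pair geodesic
        for v in sub.graph.nodes():
            if v in hubs:
                continue
            on_some = False
            for i, s in enumerate(hubs):
                for t in hubs[i + 1:]:
                    if not nx.has_path(g, s, t):
                        continue
                    if any(v in p for p in nx.all_shortest_paths(g, s, t)):
                        on_some = True
            assert on_some, v
        # every edge used comes from the host graph
        for a, b in sub.graph.edges():
            assert g.has_edge(a, b)

    def test_disconnected_hub_pair_contributes_nothing(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_edge("X", "Y")
        sub = extract_hub_subnetwork(g, ["A", "X"], "geodesic_union")
        assert set(sub.graph.nodes()) == {"A", "X"}
        assert sub.graph.number_of_edges() == 0
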