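import networkx as nx
import numpy as np
import pytest

from hubnet.synth import (
    generate_condition_seeds,
    generate_interactome,
    generate_mirna_targets,
    plant_hubs,
)


class TestGenerateInteractome:
    def test_tree_for_m_one(self):
        g = generate_interactome(10, 1, random_seed=7)
        assert g.number_of_edges() == 9
        assert nx.is_tree(g)

    def test_edge_count_closed_form(self):
        g = generate_interactome(2000, 2, random_seed=1)
        assert g.number_of_edges() == 2 * (2000 - 2)
        assert nx.is_connected(g)

    def test_determinism(self):
        a = generate_interactome(300, 2, random_seed=11)
        b = generate_interactome(300, 2, random_seed=11)
        assert set(a.edges()) == set(b.edges())

    @pytest.mark.parametrize("n,m", [(2, 2), (5, 0)])
    def test_invalid_sizes_error(self, n, m):
        with pytest.raises(ValueError):
            generate_interactome(n, m, random_seed=0)


class TestPlantHubs:
    def test_planted_nodes_dominate_degree(self):
        g = generate_interactome(500, 2, random_seed=3)
        natural_max = max(d for _, d in g.degree())
        boosted, planted = plant_hubs(g, 4, boost_factor=5.0, random_seed=4)
        top = sorted(boosted.degree(), key=lambda kv: -kv[1])[:4]
        assert {v for v, _ in top} == set(planted)
        for v in planted:
            assert boosted.degree(v) >= 5 * natural_max

    def test_original_graph_untouched(self):
        g = generate_interactome(200, 2, random_seed=5)
        before = g.number_of_edges()
        plant_hubs(g, 2, random_seed=6)
        assert g.number_of_edges() == before


class TestGenerateConditionSeeds:
    def test_full_overlap_identical_sets(self):
        g = generate_interactome(300, 2, random_seed=1)
        sets, _ = generate_condition_seeds(
            g, 3, 20, overlap_fraction=1.0, random_seed=2
        )
        assert sets[0].members == sets[1].members == sets[2].members

    def test_zero_overlap_pairwise_disjoint(self):
        g = generate_interactome(300, 2, random_seed=1)
        sets, _ = generate_condition_seeds(
            g, 3, 20, overlap_fraction=0.0, random_seed=2
        )
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i].members & sets[j].members)

    def test_pairwise_intersections_equal_the_core(self):
        g = generate_interactome(600, 2, random_seed=1)
        sets, truth = generate_condition_seeds(
            g, 3, 50, overlap_fraction=0.2, random_seed=11
        )
        core = truth.planted_linking
        assert len(core) == 10
        for i in range(3):
            for j in range(i + 1, 3):
                assert sets[i].members & sets[j].members == core

    def test_must_include_forced_into_every_condition(self):
        g = generate_interactome(300, 2, random_seed=1)
        forced = sorted(g.nodes())[:3]
        sets, truth = generate_condition_seeds(
            g, 2, 15, overlap_fraction=0.2, random_seed=3,
            must_include=forced,
        )
        for ss in sets:
            assert set(forced) <= ss.members
        assert set(forced) <= truth.planted_linking

    def test_infeasible_sizes_error(self):
        g = generate_interactome(30, 2, random_seed=1)
        with pytest.raises(ValueError):
            generate_condition_seeds(
                g, 4, 20, overlap_fraction=0.0, random_seed=0
            )

    def test_determinism(self):
        g = generate_interactome(300, 2, random_seed=1)
        a, _ = generate_condition_seeds(g, 3, 20, 0.3, random_seed=9)
        b, _ = generate_condition_seeds(g, 3, 20, 0.3, random_seed=9)
        assert [s.members for s in a] == [s.members for s in b]


class TestGenerateMirnaTargets:
    def test_zero_mirnas_error(self):
        g = generate_interactome(50, 1, random_seed=1)
        with pytest.raises(ValueError):
            generate_mirna_targets(g, 0, random_seed=0)

    def test_determinism(self):
        g = generate_interactome(200, 2, random_seed=1)
        a = generate_mirna_targets(g, 100, 5.0, random_seed=3)
        b = generate_mirna_targets(g, 100, 5.0, random_seed=3)
        assert a.mapping == b.mapping

    def test_every_mirna_has_targets(self):
        g = generate_interactome(200, 2, random_seed=1)
        tm = generate_mirna_targets(g, 50, 1.0, random_seed=2)
        assert len(tm) == 50
        assert all(len(t) >= 1 for t in tm.mapping.values())

    def test_hub_enrichment_raises_mean_target_degree(self):
        g = generate_interactome(500, 2, random_seed=1)

        def mean_target_degree(enrich, seed):
            tm = generate_mirna_targets(
                g, 60, 5.0, hub_enrichment=enrich, random_seed=seed
            )
            degs = [
                g.degree(v) for t in tm.mapping.values() for v in t
            ]
            return np.mean(degs)

        wins = sum(
            mean_target_degree(1.0, s) > mean_target_degree(0.0, s)
            for s in range(10)
        )
        assert wins == 10
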