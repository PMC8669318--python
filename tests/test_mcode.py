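"""MCODE stages: weighting, prediction, post-processing and scoring."""

import itertools

import networkx as nx
import pytest

from netkeys.mcode import (
    MCODEParams,
    core_numbers,
    postprocess,
    predict_complexes,
    run_mcode,
    score_complex,
    select_modules,
    truncate_score,
    vertex_weights,
)
from netkeys.reference import MODULE_STATS
from netkeys.synthetic import generate_planted_complexes

from conftest import oracle_core_numbers, random_graph


def clique(labels):
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(labels, 2))
    return g


class TestCoreNumbers:
    def test_complete_graph_and_tree(self, k4):
        assert set(core_numbers(k4).values()) == {3}
        tree = nx.Graph([("A", "B"), ("B", "C"), ("B", "D"), ("D", "E")])
        assert set(core_numbers(tree).values()) == {1}

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_peeling_oracle(self, seed):
        g = random_graph(15, 0.25, seed)
        assert core_numbers(g) == oracle_core_numbers(g)

    @pytest.mark.parametrize("seed", range(30))
    def test_peeling_oracle_on_graphs_up_to_20_nodes(self, seed):
        g = random_graph(20, 0.2, 100 + seed)
        assert core_numbers(g) == oracle_core_numbers(g)


class TestVertexWeights:
    def test_clique_member(self):
        g = clique("ABCDE")
        # closed neighborhood of any member is K5: 4-core of density 1
        assert vertex_weights(g)["A"] == pytest.approx(4.0)

    def test_single_neighbor(self):
        g = nx.Graph([("A", "B")])
        assert vertex_weights(g)["A"] == pytest.approx(1.0)

    def test_star_center(self, star5):
        # closed neighborhood is the star itself: 1-core, density 8/20
        assert vertex_weights(star5)["C"] == pytest.approx(0.4)

    def test_isolated_node_weighs_zero(self):
        g = nx.Graph()
        g.add_node("A")
        g.add_edge("B", "C")
        assert vertex_weights(g)["A"] == 0.0


class TestPredictComplexes:
    def test_two_cliques_with_bridge_path(self):
        g = clique(["A1", "A2", "A3", "A4", "A5"])
        g.add_edges_from(itertools.combinations(["B1", "B2", "B3", "B4", "B5"], 2))
        g.add_edges_from([("A1", "P1"), ("P1", "P2"), ("P2", "B1")])
        complexes = predict_complexes(g)
        member_sets = [c.members for c in complexes]
        assert {"A1", "A2", "A3", "A4", "A5"} in member_sets
        assert {"B1", "B2", "B3", "B4", "B5"} in member_sets

    def test_uniform_weight_cycle_is_one_complex(self, cycle5):
        complexes = predict_complexes(cycle5)
        assert len(complexes) == 1
        assert complexes[0].members == set(cycle5.nodes)

    def test_zero_cutoff_gives_singletons(self, cycle5):
        params = MCODEParams(node_score_cutoff=0.0)
        complexes = predict_complexes(cycle5, params=params)
        assert all(c.n == 1 for c in complexes)

    def test_complexes_disjoint_and_cover_subset_of_nodes(self):
        g = random_graph(30, 0.2, 4)
        complexes = predict_complexes(g)
        seen = set()
        for c in complexes:
            assert not (c.members & seen)
            seen |= c.members
        assert seen <= set(g.nodes)


class TestPostprocess:
    def test_haircut_strips_pendant(self):
        g = clique("ABCDE")
        g.add_edge("A", "P")
        (complex_,) = [
            c for c in predict_complexes(g) if {"A", "B", "C", "D", "E"} <= c.members
        ]
        processed = postprocess(complex_, g)
        assert processed.members == set("ABCDE")

    def test_no_two_core_discarded(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        complexes = predict_complexes(g)
        assert all(postprocess(c, g) is None for c in complexes)

    def test_haircut_idempotent(self):
        g = clique("ABCDEF")
        g.add_edges_from([("A", "P1"), ("B", "P2")])
        for c in predict_complexes(g):
            once = postprocess(c, g)
            if once is None:
                continue
            twice = postprocess(once, g)
            assert twice.members == once.members

    def test_fluff_adds_dense_boundary(self):
        g = clique("ABCDE")
        g.add_edges_from([("F", "A"), ("F", "B"), ("F", "C")])
        (complex_,) = [c for c in predict_complexes(g) if "A" in c.members]
        params = MCODEParams(fluff=True, fluff_density_cutoff=0.1)
        processed = postprocess(complex_, g, params)
        assert "F" in processed.members


class TestScoring:
    @pytest.mark.parametrize(
        "module_id, expected",
        [(1, 8.8), (2, 5.15), (3, 4.85), (4, 4.69), (5, 4.37)],
    )
    def test_published_module_scores(self, module_id, expected):
        n, edges = MODULE_STATS[module_id]
        assert truncate_score(score_complex(n, edges)) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_clique_scores_its_size(self, n):
        assert score_complex(n, n * (n - 1) // 2) == pytest.approx(float(n))

    def test_truncation_not_rounding(self):
        assert truncate_score(4.375) == 4.37
        assert truncate_score(4.857) == 4.85

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            score_complex(1, 0)
        with pytest.raises(ValueError):
            score_complex(4, 7)


class TestSelectModules:
    @staticmethod
    def fake_complex(g, members, seed):
        from netkeys.mcode import MCODEComplex

        return MCODEComplex(members=set(members), seed=seed, _graph=g)

    def test_min_score_threshold_keeps_five(self):
        # complexes engineered to score {8.8, 5.15, 4.85, 4.69, 4.37, 3.9}-ish:
        # cliques score their size, so use sizes around the threshold
        g = nx.Graph()
        sizes = [9, 8, 7, 6, 5, 4]
        complexes = []
        for i, size in enumerate(sizes):
            labels = [f"M{i}_{j}" for j in range(size)]
            g.add_edges_from(itertools.combinations(labels, 2))
            complexes.append(self.fake_complex(g, labels, labels[0]))
        kept = select_modules(complexes, min_score=4.0)
        assert [c.score for c in kept] == [9, 8, 7, 6, 5]

    def test_all_below_threshold_empty(self, k4):
        c = self.fake_complex(k4, set(k4.nodes), "V0")
        assert select_modules([c], min_score=5.0) == []

    def test_tie_breaks_on_size(self):
        # n=10 with 18 edges and n=8 with 14 edges both score exactly 4.0;
        # the larger complex is listed first
        g = nx.Graph()
        a = [f"A{j}" for j in range(10)]
        b = [f"B{j}" for j in range(8)]
        g.add_edges_from(list(itertools.combinations(a, 2))[:18])
        g.add_edges_from(list(itertools.combinations(b, 2))[:14])
        c1 = self.fake_complex(g, a, "A0")
        c2 = self.fake_complex(g, b, "B0")
        assert c1.score == c2.score == pytest.approx(4.0)
        kept = select_modules([c2, c1], min_score=3.5)
        assert [c.n for c in kept] == [10, 8]


class TestPlantedRecovery:
    def jaccard(self, a, b):
        return len(a & b) / len(a | b)

    def test_single_planted_clique_recovered_exactly(self):
        g, plants = generate_planted_complexes(100, 0.02, [(6, 1.0)], seed=2)
        modules = run_mcode(g)
        assert modules, "no module found"
        best = max(modules, key=lambda c: self.jaccard(c.members, plants["plant_1"]))
        assert self.jaccard(best.members, plants["plant_1"]) == 1.0

    def test_two_dense_plants_recovered(self):
        g, plants = generate_planted_complexes(
            150, 0.02, [(8, 0.9), (10, 0.9)], seed=3
        )
        modules = run_mcode(g)
        for plant in plants.values():
            best = max(self.jaccard(c.members, plant) for c in modules)
            assert best >= 0.8

    def test_no_plants_no_modules_above_threshold(self):
        g, _ = generate_planted_complexes(100, 0.02, [], seed=4)
        assert run_mcode(g) == []
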