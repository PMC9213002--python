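import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import Delaunay

from nucalign import (LandmarkCloud, LineageEvent, compile_inconsistent,
                      consistency_profile, consistent_adjacencies,
                      gabriel_graph, score_assignment)
from nucalign.adjacency import AdjacencyGraph

from conftest import brute_force_gabriel


def graph_of(edges, nodes=None):
    nodes = nodes if nodes is not None else {n for e in edges for n in e}
    return AdjacencyGraph(frozenset(nodes), frozenset(map(tuple, edges)))


class TestGabriel:
    def test_collinear_midpoint_deletes_long_edge(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        g = gabriel_graph(pts)
        assert g.edges == {(0, 1), (1, 2)}

    def test_equilateral_triangle_keeps_all_edges(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        g = gabriel_graph(pts)
        assert g.edges == {(0, 1), (0, 2), (1, 2)}
        assert g.edges == brute_force_gabriel(pts)

    def test_obtuse_triangle_drops_the_blocked_edge(self):
        pts = np.array([[0, 0, 0], [4, 0, 0], [1, 1, 0]], float)
        g = gabriel_graph(pts)
        # witness for edge 0-1: |p0-p2|^2 + |p1-p2|^2 = 2 + 10 < 16
        assert g.edges == {(0, 2), (1, 2)}
        assert g.edges == brute_force_gabriel(pts)

    def test_matches_brute_force_oracle_on_random_clouds(self):
        for seed in range(20):
            pts = np.random.default_rng(seed).uniform(0, 1, size=(30, 3))
            assert gabriel_graph(pts).edges == brute_force_gabriel(pts)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=4, max_value=15))
    def test_matches_brute_force_oracle_property(self, seed, n):
        pts = np.random.default_rng(seed).normal(size=(n, 3))
        assert gabriel_graph(pts).edges == brute_force_gabriel(pts)

    def test_subset_of_delaunay_in_general_position(self, rng):
        pts = rng.uniform(0, 1, size=(40, 3))
        tri = Delaunay(pts)
        delaunay = set()
        for s in tri.simplices:
            for a in range(4):
                for b in range(a + 1, 4):
                    delaunay.add((min(s[a], s[b]), max(s[a], s[b])))
        assert gabriel_graph(pts).edges <= delaunay

    def test_named_cloud_gives_name_nodes(self, generic_cloud):
        g = gabriel_graph(generic_cloud)
        assert g.nodes == set(generic_cloud.names)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gabriel_graph(np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]], float))

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            gabriel_graph(np.array([[0.0, 0.0, 0.0]]))


class TestConsistency:
    def test_intersection_of_edge_sets(self):
        gs = [graph_of({("A", "B"), ("B", "C")}),
              graph_of({("A", "B"), ("B", "C"), ("A", "C")}),
              graph_of({("A", "B"), ("B", "C")})]
        assert consistent_adjacencies(gs).edges == {("A", "B"), ("B", "C")}

    def test_single_graph_is_its_own_consistency(self):
        g = graph_of({("A", "B")})
        assert consistent_adjacencies([g]).edges == g.edges

    def test_disjoint_graphs_share_nothing(self):
        gs = [graph_of({("A", "B")}), graph_of({("C", "D")})]
        assert consistent_adjacencies(gs).edges == set()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consistent_adjacencies([])

    def test_profile_fractions_and_unanimous_edges(self, rng):
        gs = [graph_of({("A", "B"), ("B", "C")}),
              graph_of({("A", "B"), ("A", "C")}),
              graph_of({("A", "B"), ("B", "C")})]
        prof = consistency_profile(gs)
        assert prof[("A", "B")] == pytest.approx(1.0)
        assert prof[("A", "C")] == pytest.approx(1 / 3)
        unanimous = {e for e, f in prof.items() if f == 1.0}
        assert unanimous == consistent_adjacencies(gs).edges

    def test_profile_matches_consistency_on_random_graphs(self, rng):
        names = [f"c{i}" for i in range(8)]
        gs = []
        for _ in range(4):
            pts = rng.uniform(0, 1, size=(8, 3))
            gs.append(gabriel_graph(LandmarkCloud(points=pts, names=tuple(names))))
        prof = consistency_profile(gs)
        assert all(0 < f <= 1 for f in prof.values())
        assert {e for e, f in prof.items() if f == 1.0} == consistent_adjacencies(gs).edges


class TestCompileInconsistent:
    def test_window_is_centered_on_stage_time(self):
        inside = LineageEvent(kind="division", subject="a", daughters=("a1", "a2"),
                              time=318.0)
        outside = LineageEvent(kind="death", subject="b", time=300.0)
        out = compile_inconsistent([inside, outside], stage_time=320.0, window=13.0)
        assert out == [inside]

    def test_divisions_precede_deaths_each_sorted_by_subject(self):
        evs = [
            LineageEvent(kind="death", subject="z", time=100.0),
            LineageEvent(kind="division", subject="m", daughters=("m1", "m2"), time=100.0),
            LineageEvent(kind="death", subject="a", time=100.0),
            LineageEvent(kind="division", subject="b", daughters=("b1", "b2"), time=100.0),
        ]
        out = compile_inconsistent(evs, 100.0, 13.0)
        assert [(e.kind, e.subject) for e in out] == [
            ("division", "b"), ("division", "m"), ("death", "a"), ("death", "z")]


class TestScoreAssignment:
    def test_worked_example_charges_both_endpoints(self):
        consistent = graph_of({("A", "B"), ("B", "C")})
        unlabeled = graph_of({(0, 1)}, nodes={0, 1, 2})
        score = score_assignment({0: "A", 1: "B", 2: "C"}, consistent, unlabeled)
        assert score.total == 1
        assert dict(score.per_identity) == {"B": 1, "C": 1}

    def test_perfect_mirror_scores_zero(self):
        consistent = graph_of({("A", "B"), ("B", "C")})
        unlabeled = graph_of({(0, 1), (1, 2)}, nodes={0, 1, 2})
        score = score_assignment({0: "A", 1: "B", 2: "C"}, consistent, unlabeled)
        assert score.total == 0
        assert not score.per_identity

    def test_unassigned_identity_counts_as_missing(self):
        consistent = graph_of({("A", "B")})
        unlabeled = graph_of(set(), nodes={0})
        score = score_assignment({0: "B"}, consistent, unlabeled)
        assert score.total == 1
        assert dict(score.per_identity) == {"A": 1, "B": 1}

    def test_duplicate_identity_satisfied_by_any_adjacent_pair(self):
        consistent = graph_of({("A", "B")})
        unlabeled = graph_of({(1, 2)}, nodes={0, 1, 2})
        # A assigned twice via alias; only the second copy is adjacent to B
        score = score_assignment({0: "A1", 1: "A2", 2: "B"}, consistent, unlabeled,
                                 aliases={"A": ("A1", "A2")})
        assert score.total == 0

    def test_total_invariant_under_index_relabeling(self, rng):
        names = [f"c{i}" for i in range(10)]
        pts = rng.uniform(0, 1, size=(10, 3))
        consistent = gabriel_graph(LandmarkCloud(points=pts, names=tuple(names)))
        upts = pts + rng.normal(scale=0.02, size=pts.shape)
        ug = gabriel_graph(upts)
        mapping = {i: names[i] for i in range(10)}
        base = score_assignment(mapping, consistent, ug).total
        perm = rng.permutation(10)
        ug2 = gabriel_graph(upts[perm])
        inv = np.argsort(perm)
        mapping2 = {int(inv[i]): names[i] for i in range(10)}
        assert score_assignment(mapping2, consistent, ug2).total == base

    def test_per_identity_sums_to_twice_total(self, rng):
        names = [f"c{i}" for i in range(12)]
        pts = rng.uniform(0, 1, size=(12, 3))
        consistent = gabriel_graph(LandmarkCloud(points=pts, names=tuple(names)))
        ug = gabriel_graph(pts + rng.normal(scale=0.05, size=pts.shape))
        score = score_assignment({i: names[i] for i in range(12)}, consistent, ug)
        assert sum(score.per_identity.values()) == 2 * score.total
        assert score.total <= len(consistent.edges)
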