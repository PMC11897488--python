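import numpy as np
import pytest

from topobrain.graph_ph import (
    build_filter,
    extended_persistence_1,
    ordinary_persistence_0,
)

from conftest import make_graph, random_weighted_graph
from _oracles import extended_persistence_oracle


def pairs(dgm):
    return sorted(map(tuple, dgm.pairs.tolist()))


class TestBuildFilter:
    def test_vertex_value_is_min_incident_edge(self):
        g = make_graph({("a", "b"): 1, ("b", "c"): 4, ("c", "d"): 2})
        f = build_filter(g)
        assert f.vertex_value == {"a": 1, "b": 1, "c": 2, "d": 2}
        assert f.edge_value[("a", "b")] == 1

    def test_one_minus_w_transform(self):
        g = make_graph({("a", "b"): 0.3})
        f = build_filter(g, "one_minus_w")
        assert f.edge_value[("a", "b")] == pytest.approx(0.7)

    def test_single_edge_endpoints_share_its_value(self):
        g = make_graph({("a", "b"): 5})
        f = build_filter(g)
        assert f.vertex_value == {"a": 5, "b": 5}

    def test_isolated_vertex_convention(self):
        g = make_graph({("a", "b"): 2}, extra_nodes=["z"])
        f = build_filter(g)
        assert f.vertex_value["z"] == 0.0


class TestOrdinaryPersistence:
    def test_two_components_merging(self, fig_style_path_graph):
        """Components born at 1 and 2 merge at 4: Dg0 = {(2, 4), (1, inf)}."""
        dgm = ordinary_persistence_0(build_filter(fig_style_path_graph))
        assert pairs(dgm) == [(1.0, np.inf), (2.0, 4.0)]

    def test_single_vertex(self):
        g = make_graph({}, extra_nodes=["v"])
        dgm = ordinary_persistence_0(build_filter(g))
        assert pairs(dgm) == [(0.0, np.inf)]

    def test_uniform_tree_has_only_the_essential_class(self):
        g = make_graph({("a", "b"): 3, ("b", "c"): 3, ("b", "d"): 3})
        dgm = ordinary_persistence_0(build_filter(g))
        assert pairs(dgm) == [(3.0, np.inf)]
        with_zeros = ordinary_persistence_0(build_filter(g), keep_zero=True)
        zero = with_zeros.pairs[np.isfinite(with_zeros.deaths)]
        assert np.all(zero[:, 0] == zero[:, 1])

    def test_essential_count_equals_component_count(self, rng):
        for _ in range(20):
            g = random_weighted_graph(rng, p_edge=0.3)
            dgm = ordinary_persistence_0(build_filter(g))
            assert dgm.essential_count == g.n_components

    def test_finite_pairs_have_birth_below_death(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng)
            dgm = ordinary_persistence_0(build_filter(g))
            fin = dgm.pairs[np.isfinite(dgm.deaths)]
            assert np.all(fin[:, 0] < fin[:, 1])


class TestExtendedPersistence:
    def test_lone_cycle_pairs_max_with_min(self):
        """A 3-cycle with edge values 4, 5, 7 is the single point (7, 4)."""
        g = make_graph({("x", "y"): 4, ("y", "z"): 5, ("x", "z"): 7})
        dgm = extended_persistence_1(build_filter(g))
        assert pairs(dgm) == [(7.0, 4.0)]

    def test_tree_has_no_cycles(self, rng):
        g = make_graph({("a", "b"): 1, ("b", "c"): 5, ("c", "d"): 2,
                        ("b", "e"): 7})
        assert len(extended_persistence_1(build_filter(g))) == 0

    @pytest.mark.parametrize("trial", range(50))
    def test_shared_edge_triangles_match_matrix_reduction_oracle(self, trial):
        """Two triangles sharing an edge, random integer filter values."""
        rng = np.random.default_rng(2000 + trial)
        vals = rng.integers(1, 9, size=5).astype(float)
        g = make_graph({("a", "b"): vals[0], ("b", "c"): vals[1],
                        ("a", "c"): vals[2], ("b", "d"): vals[3],
                        ("c", "d"): vals[4]})
        f = build_filter(g)
        got = pairs(extended_persistence_1(f))
        want = sorted(extended_persistence_oracle(g.nodes, f.edge_value))
        assert np.allclose(np.array(got).reshape(-1, 2),
                           np.array(want).reshape(-1, 2))

    @pytest.mark.parametrize("trial", range(30))
    def test_random_graphs_match_matrix_reduction_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        g = random_weighted_graph(rng, max_nodes=10)
        f = build_filter(g)
        got = pairs(extended_persistence_1(f))
        want = sorted(extended_persistence_oracle(g.nodes, f.edge_value))
        assert np.allclose(np.array(got).reshape(-1, 2),
                           np.array(want).reshape(-1, 2))

    def test_point_count_is_the_first_betti_number(self, rng):
        for _ in range(20):
            g = random_weighted_graph(rng, p_edge=0.4, integer=False)
            dgm = extended_persistence_1(build_filter(g))
            betti1 = len(g.edges) - len(g.nodes) + g.n_components
            assert len(dgm) == betti1

    def test_births_dominate_deaths(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, integer=False)
            dgm = extended_persistence_1(build_filter(g))
            assert np.all(dgm.births >= dgm.deaths)

    def test_tie_robustness_under_node_relabelling(self, rng):
        """Permuting node names (hence tie-break order) keeps the multiset."""
        for trial in range(10):
            g = random_weighted_graph(rng, max_nodes=8, integer=True)
            perm = {n: f"m{i}" for i, n in
                    enumerate(rng.permutation(g.nodes))}
            g2 = make_graph({(perm[a], perm[b]): w
                             for (a, b), w in g.edges.items()},
                            extra_nodes=[perm[n] for n in g.nodes])
            d1 = extended_persistence_1(build_filter(g))
            d2 = extended_persistence_1(build_filter(g2))
            assert pairs(d1) == pairs(d2)
            o1 = ordinary_persistence_0(build_filter(g))
            o2 = ordinary_persistence_0(build_filter(g2))
            assert pairs(o1) == pairs(o2)
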