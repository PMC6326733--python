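"""Graph metrics against independent (networkx / brute-force) oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from connsim.groundtruth import generate_partition
from connsim.metrics import (
    PathLengthResult,
    UndefinedSigmaError,
    attempted_swap_budget,
    char_path_length,
    degree,
    module_degree,
    rewire_preserving_degree,
    small_worldness,
    strength,
    transitivity,
    zscore_by_module_density,
)


def all_graphs(n):
    """Every labeled simple graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(1, 2 ** len(pairs)):
        adj = np.zeros((n, n))
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                adj[i, j] = adj[j, i] = 1.0
        yield adj


class TestOracleEquivalence:
    def test_exhaustive_small_graphs_match_networkx(self):
        # every labeled graph on 4 nodes: degree, transitivity, path length
        for adj in all_graphs(4):
            g = nx.from_numpy_array(adj)
            np.testing.assert_array_equal(degree(adj), [d for _, d in sorted(g.degree)])
            assert transitivity(adj) == pytest.approx(nx.transitivity(g))
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            dists = [
                lengths[i][j]
                for i in g for j in g
                if i != j and j in lengths[i]
            ]
            if dists:
                ours = char_path_length(adj)
                assert ours.length == pytest.approx(np.mean(dists))
                assert ours.n_unreachable_pairs == 4 * 3 - len(dists)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_8node_graphs_match_networkx(self, seed):
        g = nx.gnp_random_graph(8, 0.5, seed=seed)
        if g.number_of_edges() == 0:
            return
        adj = nx.to_numpy_array(g)
        np.testing.assert_array_equal(degree(adj), [d for _, d in sorted(g.degree)])
        assert transitivity(adj) == pytest.approx(nx.transitivity(g))
        if nx.is_connected(g):
            assert char_path_length(adj).length == pytest.approx(
                nx.average_shortest_path_length(g)
            )


class TestDegreeStrength:
    def test_star_graph(self):
        adj = nx.to_numpy_array(nx.star_graph(4))
        np.testing.assert_array_equal(degree(adj), [4, 1, 1, 1, 1])

    def test_handshake_lemma(self, rng):
        adj = nx.to_numpy_array(nx.gnp_random_graph(20, 0.3, seed=9))
        assert degree(adj).sum() == 2 * adj.sum() / 2

    def test_degree_rejects_weighted(self):
        adj = np.array([[0, 0.5], [0.5, 0]])
        with pytest.raises(TypeError):
            degree(adj)

    def test_strength_reduces_to_degree_on_binary(self):
        adj = nx.to_numpy_array(nx.cycle_graph(6))
        np.testing.assert_array_equal(strength(adj), degree(adj))

    def test_strength_weighted_toy(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.2
        adj[0, 2] = adj[2, 0] = 0.3
        adj[1, 2] = adj[2, 1] = 0.5
        np.testing.assert_allclose(strength(adj), [0.5, 0.7, 0.8])


class TestModuleDegree:
    def test_within_plus_between_equals_degree(self, rng):
        part = generate_partition(20, module_sizes=[8, 7, 5])
        adj = nx.to_numpy_array(nx.gnp_random_graph(20, 0.4, seed=3))
        w = module_degree(adj, part, "within")
        b = module_degree(adj, part, "between")
        np.testing.assert_array_equal(w + b, degree(adj))

    def test_brute_force_edge_classification(self):
        part = generate_partition(6, module_sizes=[3, 3])
        adj = nx.to_numpy_array(nx.gnp_random_graph(6, 0.6, seed=4))
        w_expected = np.zeros(6, dtype=int)
        b_expected = np.zeros(6, dtype=int)
        for i in range(6):
            for j in range(6):
                if i != j and adj[i, j]:
                    if part.assignments[i] == part.assignments[j]:
                        w_expected[i] += 1
                    else:
                        b_expected[i] += 1
        np.testing.assert_array_equal(module_degree(adj, part, "within"), w_expected)
        np.testing.assert_array_equal(module_degree(adj, part, "between"), b_expected)

    def test_intra_module_only_graph_has_zero_between(self):
        part = generate_partition(6, module_sizes=[3, 3])
        adj = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            adj[i, j] = adj[j, i] = 1
        assert module_degree(adj, part, "between").sum() == 0

    def test_partition_mismatch_rejected(self):
        part = generate_partition(6, module_sizes=[3, 3])
        with pytest.raises(ValueError):
            module_degree(np.zeros((5, 5)), part, "within")


class TestZScore:
    def test_hand_computed_stratum(self):
        import pandas as pd

        df = pd.DataFrame({
            "module": ["A"] * 3, "density": [0.1] * 3, "value": [2.0, 4.0, 6.0],
        })
        out = zscore_by_module_density(df)
        np.testing.assert_allclose(out.z, [-1, 0, 1])

    def test_every_stratum_standardized(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "module": np.repeat(["A", "B"], 40),
            "density": np.tile(np.repeat([0.1, 0.2], 20), 2),
            "value": rng.normal(5, 2, 80),
        })
        out = zscore_by_module_density(df)
        g = out.groupby(["module", "density"]).z
        np.testing.assert_allclose(g.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(g.std(), 1, atol=1e-12)

    def test_zero_variance_stratum_flagged_not_dropped(self):
        import pandas as pd

        df = pd.DataFrame({
            "module": ["A"] * 2 + ["B"] * 2,
            "density": [0.1] * 4,
            "value": [3.0, 3.0, 1.0, 2.0],
        })
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore_by_module_density(df)
        assert out.zero_variance.tolist() == [True, True, False, False]
        assert out.z.isna().tolist() == [True, True, False, False]


class TestTransitivityPathLength:
    def test_complete_graph_k4(self):
        assert transitivity(nx.to_numpy_array(nx.complete_graph(4))) == 1.0

    def test_path_graph_no_triangles(self):
        assert transitivity(nx.to_numpy_array(nx.path_graph(4))) == 0.0

    def test_no_triples_warns_and_returns_zero(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        with pytest.warns(UserWarning, match="triples"):
            assert transitivity(adj) == 0.0

    def test_complete_graph_path_length_one(self):
        assert char_path_length(nx.to_numpy_array(nx.complete_graph(7))).length == 1.0

    def test_ring_of_five(self):
        # distances from any node: 1,1,2,2 -> mean 1.5
        assert char_path_length(nx.to_numpy_array(nx.cycle_graph(5))).length == 1.5

    def test_two_triangles_report_unreachable_pairs(self):
        adj = np.zeros((6, 6))
        for c in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(c, 2):
                adj[i, j] = adj[j, i] = 1
        res = char_path_length(adj)
        assert res == PathLengthResult(1.0, 18)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        adj = nx.to_numpy_array(nx.gnp_random_graph(20, 0.3, seed=11))
        out = rewire_preserving_degree(adj, rng=rng)
        np.testing.assert_array_equal(degree(out), degree(adj))
        assert out.sum() == adj.sum()  # edge count conserved

    def test_triangle_is_rigid(self):
        adj = nx.to_numpy_array(nx.complete_graph(3))
        out = rewire_preserving_degree(adj, rng=0)
        np.testing.assert_array_equal(out, adj)

    def test_rewiring_randomizes_clustering(self):
        adj = nx.to_numpy_array(nx.watts_strogatz_graph(100, 8, 0.02, seed=5))
        out = rewire_preserving_degree(adj, rng=1)
        assert transitivity(out) < transitivity(adj) / 3

    def test_swap_budget_modes(self):
        # the 'pairs' budget reproduces the 10-per-unique-pair convention
        assert attempted_swap_budget(264, 8679, 10, "pairs") == 347160
        assert attempted_swap_budget(264, 8679, 10, "edges") == 86790

    def test_determinism(self):
        adj = nx.to_numpy_array(nx.gnp_random_graph(30, 0.3, seed=12))
        a = rewire_preserving_degree(adj, rng=42)
        b = rewire_preserving_degree(adj, rng=42)
        np.testing.assert_array_equal(a, b)


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        res = small_worldness(nx.to_numpy_array(nx.complete_graph(12)), n_null=3, rng=0)
        assert res.sigma == 1.0
        assert res.C_g == res.C_rand == 1.0
        assert res.L_g == res.L_rand == 1.0

    def test_erdos_renyi_is_its_own_null(self):
        adj = nx.to_numpy_array(nx.gnp_random_graph(200, 0.1, seed=21))
        res = small_worldness(adj, n_null=20, rng=2)
        assert abs(res.sigma - 1.0) < 0.1

    def test_watts_strogatz_strongly_small_world(self):
        adj = nx.to_numpy_array(nx.watts_strogatz_graph(200, 10, 0.05, seed=22))
        res = small_worldness(adj, n_null=20, rng=3)
        assert res.sigma > 1.5

    def test_sigma_invariant_to_node_relabeling(self):
        adj = nx.to_numpy_array(nx.watts_strogatz_graph(80, 6, 0.1, seed=23))
        perm = np.random.default_rng(4).permutation(80)
        res_a = small_worldness(adj, n_null=30, rng=5)
        res_b = small_worldness(adj[np.ix_(perm, perm)], n_null=30, rng=6)
        # identical C_g/L_g; null means agree within ensemble spread
        assert res_a.C_g == pytest.approx(res_b.C_g)
        assert res_a.L_g == pytest.approx(res_b.L_g)
        assert res_a.sigma == pytest.approx(res_b.sigma, rel=0.1)

    def test_disconnected_graph_uses_largest_component(self):
        adj = np.zeros((12, 12))
        ws = nx.to_numpy_array(nx.watts_strogatz_graph(9, 4, 0.2, seed=24))
        adj[:9, :9] = ws
        for i, j in [(9, 10), (10, 11), (9, 11)]:
            adj[i, j] = adj[j, i] = 1
        res = small_worldness(adj, n_null=3, rng=7)
        assert res.component_coverage == pytest.approx(9 / 12)

    def test_sigma_undefined_without_triangles_in_null(self):
        # a single path graph cannot produce null transitivity > 0
        adj = nx.to_numpy_array(nx.path_graph(5))
        with pytest.raises(UndefinedSigmaError):
            small_worldness(adj, n_null=2, rng=8)
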