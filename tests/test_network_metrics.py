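import networkx as nx
import numpy as np
import pytest

from ecmgraph import (
    WUCM,
    UndefinedMetricError,
    balance_test,
    characteristic_path_length,
    lattice_null,
    random_null,
    small_world_propensity,
    total_strength,
    weighted_assortativity,
    weighted_clustering,
)

from conftest import random_wdcm, random_wucm
import oracles


def wucm(matrix):
    m = np.asarray(matrix, float)
    return WUCM(m, tuple(f"n{i}" for i in range(len(m))))


TRIANGLE = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
PATH3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]


class TestStrength:
    def test_ordered_vs_pair_sum(self):
        u = wucm([[0, 0.3], [0.3, 0]])
        assert total_strength(u, "ordered_sum").s == pytest.approx(0.6)
        assert total_strength(u, "pair_sum").s == pytest.approx(0.3)

    def test_zero_matrix(self):
        u = wucm(np.zeros((4, 4)))
        assert total_strength(u).s == 0.0
        assert total_strength(u, "pair_sum").s == 0.0


class TestClustering:
    def test_unit_triangle_is_one(self):
        assert weighted_clustering(wucm(TRIANGLE)) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        assert weighted_clustering(wucm(PATH3)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [4, 6, 9, 12])
    def test_matches_triple_enumeration_oracle(self, n, seed):
        u = random_wucm(n, np.random.default_rng(seed), density=0.7)
        ours = weighted_clustering(u)
        assert ours == pytest.approx(
            oracles.clustering_by_triple_enumeration(u.matrix), abs=1e-10
        )

    def test_matches_networkx(self):
        u = random_wucm(10, np.random.default_rng(42), density=0.6)
        g = nx.from_numpy_array(u.matrix)
        ref = np.mean(list(nx.clustering(g, weight="weight").values()))
        assert weighted_clustering(u) == pytest.approx(ref, abs=1e-12)


class TestPathLength:
    def test_two_nodes_inverse_weight(self):
        assert characteristic_path_length(wucm([[0, 0.5], [0.5, 0]])) == pytest.approx(2.0)

    def test_unit_triangle(self):
        assert characteristic_path_length(wucm(TRIANGLE)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_simple_path_enumeration(self, seed):
        u = random_wucm(5, np.random.default_rng(seed), density=0.8)
        assert characteristic_path_length(u, "ignore") == pytest.approx(
            oracles.path_length_by_enumeration(u.matrix), abs=1e-10
        )

    def test_disconnected_pairs_excluded_with_warning(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 0.5
        with pytest.warns(UserWarning, match="disconnected"):
            L = characteristic_path_length(wucm(m))
        assert L == pytest.approx((1.0 + 1.0 + 2.0 + 2.0) / 4)

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(wucm(np.zeros((3, 3))))


class TestNulls:
    def test_lattice_is_fixed_point_and_conserves_weights(self):
        u = random_wucm(12, np.random.default_rng(7))
        latt = lattice_null(u)
        np.testing.assert_array_equal(lattice_null(latt).matrix, latt.matrix)
        iu = np.triu_indices(12, 1)
        np.testing.assert_allclose(
            np.sort(latt.matrix[iu]), np.sort(u.matrix[iu]), rtol=0
        )

    def test_lattice_concentrates_clustering(self):
        # lattice surrogate should out-cluster the random surrogate
        wins = 0
        for seed in range(100):
            u = random_wucm(16, np.random.default_rng(seed), density=0.4)
            c_latt = weighted_clustering(lattice_null(u))
            c_rand = weighted_clustering(random_null(u, seed))
            wins += c_latt >= c_rand
        assert wins == 100

    def test_random_null_seeded_and_conserving(self):
        u = random_wucm(10, np.random.default_rng(3))
        a = random_null(u, 11)
        b = random_null(u, 11)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        iu = np.triu_indices(10, 1)
        np.testing.assert_allclose(np.sort(a.matrix[iu]), np.sort(u.matrix[iu]))
        assert a.matrix.mean() == pytest.approx(u.matrix.mean())


class TestSwp:
    def test_lattice_identical_graph(self):
        # dC = 0, dL = 1 after clipping: SWP = 1 - 1/sqrt(2)
        u = lattice_null(random_wucm(20, np.random.default_rng(0), density=0.3))
        res = small_world_propensity(u, n_null=100, seed=1)
        assert res.dC == pytest.approx(0.0, abs=1e-12)
        assert res.dL == pytest.approx(1.0, abs=1e-12)
        assert res.swp_mean == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-9)

    def test_bounded_and_seed_deterministic(self):
        u = random_wucm(15, np.random.default_rng(2), density=0.5)
        a = small_world_propensity(u, n_null=50, seed=9)
        b = small_world_propensity(u, n_null=50, seed=9)
        assert a == b
        assert 0.0 <= a.swp_mean <= 1.0
        assert 0.0 <= a.dC <= 1.0 and 0.0 <= a.dL <= 1.0


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self):
        m = np.zeros((4, 4))
        m[0, 1:] = m[1:, 0] = 1.0
        u = wucm(m)
        assert weighted_assortativity(u) == pytest.approx(-1.0)
        assert weighted_assortativity(u) == pytest.approx(
            oracles.assortativity_by_edge_list(m), abs=1e-12
        )

    def test_regular_graph_undefined(self):
        m = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
            m[a, b] = m[b, a] = 1.0
        with pytest.raises(UndefinedMetricError, match="zero variance"):
            weighted_assortativity(wucm(m))

    @pytest.mark.parametrize("mode", ["out-in", "out-out", "in-in"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_list_oracle_directed(self, seed, mode):
        w = random_wdcm(9, np.random.default_rng(seed), density=0.6)
        assert weighted_assortativity(w, mode=mode) == pytest.approx(
            oracles.assortativity_by_edge_list(w.matrix, mode=mode), abs=1e-10
        )

    def test_subset_and_subset_strengths_match_oracle(self):
        rng = np.random.default_rng(31)
        w = random_wdcm(10, rng, density=0.7)
        edges = [(i, j) for i in range(5) for j in range(10) if i != j]
        for strengths in ("full", "subset"):
            assert weighted_assortativity(
                w, edges=edges, endpoint_strengths=strengths
            ) == pytest.approx(
                oracles.assortativity_by_edge_list(
                    w.matrix, edges=edges, endpoint_strengths=strengths
                ),
                abs=1e-10,
            )


class TestBalance:
    def test_all_zero_differences(self):
        r = balance_test(np.zeros(10))
        assert r.p_value == 1.0 and r.neg_log10_p == 0.0 and r.t_stat == 0.0

    def test_exactly_balanced_alternating(self):
        r = balance_test(np.array([0.1, -0.1] * 5))
        assert r.t_stat == pytest.approx(0.0, abs=1e-15)
        assert r.p_value == pytest.approx(1.0)
        assert r.neg_log10_p == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_t_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.02, 0.1, 30)
        r = balance_test(x)
        t_ref, p_ref = oracles.t_test_p_by_integration(x)
        assert r.t_stat == pytest.approx(t_ref, abs=1e-12)
        assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_nonzero_mean_capped(self):
        r = balance_test(np.full(5, 0.3))
        assert r.degenerate
        assert r.p_value == 1e-16
        assert r.neg_log10_p == pytest.approx(16.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            balance_test(np.array([0.1]))
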