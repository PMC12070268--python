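"""Cluster-permutation machinery: t-maps, cluster formation, Monte
Carlo p-values, and the exact sign-flip enumeration oracle."""
import itertools

import numpy as np
import pytest
from scipy import stats

from eegbind import clusterperm as cp
from eegbind import synthgen as sg


def chain_adjacency(n):
    m = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = True
    return cp.Adjacency(matrix=m)


class TestAdjacency:
    def test_sensor_graph_properties(self, array32, adjacency32):
        m = adjacency32.matrix
        assert (m == m.T).all()
        assert not m.diagonal().any()
        assert 5 <= np.median(m.sum(axis=1)) <= 9

    def test_grid_26_connectivity(self):
        pos = np.array([[x, y, z] for x in range(3) for y in range(3) for z in range(3)], float) * 10
        adj = cp.grid_adjacency(pos, 10.0)
        center = 13  # (1,1,1)
        assert adj.matrix[center].sum() == 26

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 1] = True
        with pytest.raises(ValueError):
            cp.Adjacency(matrix=m)


class TestElementwiseT:
    def test_identical_paired_conditions_zero(self):
        a = np.random.default_rng(0).normal(size=(6, 4))
        t = cp.elementwise_t(a, a.copy(), "dependent")
        np.testing.assert_array_equal(t, 0.0)

    def test_constant_difference_capped(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[0.0], [1.0], [2.0]])
        t = cp.elementwise_t(a, b, "dependent")
        assert t[0] == cp.T_CAP

    def test_matches_scipy_formula(self, rng):
        a = rng.normal(size=(8, 5))
        b = rng.normal(size=(8, 5))
        np.testing.assert_allclose(
            cp.elementwise_t(a, b, "dependent"),
            stats.ttest_rel(a, b, axis=0).statistic,
        )
        c = rng.normal(size=(6, 5))
        np.testing.assert_allclose(
            cp.elementwise_t(a, c, "independent"),
            stats.ttest_ind(a, c, axis=0).statistic,
        )

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            cp.elementwise_t(np.ones((1, 3)), np.ones((1, 3)), "dependent")


class TestFormClusters:
    def test_zero_map_empty(self):
        cs = cp.form_clusters(np.zeros(5), 2.0, chain_adjacency(5))
        assert cs.clusters == []

    def test_chain_components_by_hand(self):
        # chain a-b-c, t = (3, 3, -3), threshold 2 -> {a,b} (+6) and {c} (-3)
        cs = cp.form_clusters(np.array([3.0, 3.0, -3.0]), 2.0, chain_adjacency(3))
        assert len(cs.clusters) == 2
        pos = next(c for c in cs.clusters if c.sign == 1)
        neg = next(c for c in cs.clusters if c.sign == -1)
        assert sorted(pos.nodes) == [0, 1] and pos.t_sum == pytest.approx(6.0)
        assert sorted(neg.nodes) == [2] and neg.t_sum == pytest.approx(-3.0)

    def test_nonadjacent_nodes_stay_separate(self):
        cs = cp.form_clusters(np.array([3.0, 0.0, 3.0]), 2.0, chain_adjacency(3))
        assert len(cs.clusters) == 2
        assert all(len(c.nodes) == 1 for c in cs.clusters)

    def test_min_neighbor_rule_suppresses_singletons(self):
        # triangle of suprathreshold nodes survives, isolated node does not
        m = np.zeros((5, 5), dtype=bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4)]:
            m[i, j] = m[j, i] = True
        adj = cp.Adjacency(matrix=m)
        t = np.array([3.0, 3.0, 3.0, 3.0, 0.0])
        cs = cp.form_clusters(t, 2.0, adj, min_neighbors=2)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0].nodes) == [0, 1, 2]

    def test_t_sum_exact(self, rng, adjacency32):
        t = rng.normal(scale=3, size=adjacency32.n_nodes)
        cs = cp.form_clusters(t, 2.0, adjacency32)
        for c in cs.clusters:
            assert c.t_sum == pytest.approx(t[c.nodes].sum(), abs=1e-12)
            assert np.all(np.sign(t[c.nodes]) == c.sign)


class TestPermutationTest:
    def test_planted_effect_detected(self, rng, adjacency32):
        n = 12
        a = rng.normal(size=(n, 32))
        b = rng.normal(size=(n, 32))
        seeded = [0, 1, 2, 3]  # named channels are mutually adjacent
        a[:, seeded] += 1.5
        cs = cp.permutation_test(a, b, "dependent", adjacency32, R=500, seed=0)
        sig = cs.significant()
        assert sig
        assert set(seeded) & set(sig[0].nodes)

    def test_min_p_is_estimator_bound(self, rng, adjacency32):
        a = rng.normal(size=(16, 32))
        b = a - 5.0 + 0.3 * rng.normal(size=(16, 32))  # overwhelming effect
        cs = cp.permutation_test(a, b, "dependent", adjacency32, R=99, seed=0)
        assert min(c.p for c in cs.clusters) == pytest.approx(1.0 / 100.0)

    def test_null_group_contrast_rarely_significant(self, rng, adjacency32):
        rejections = 0
        for rep in range(20):
            a = rng.normal(size=(10, 32))
            b = rng.normal(size=(10, 32))
            cs = cp.between_group_contrast_test(a, b, adjacency32, R=200, seed=rep)
            rejections += bool(cs.significant())
        assert rejections <= 4

    def test_relabelling_invariance(self, rng, adjacency32):
        a = rng.normal(size=(8, 32))
        b = rng.normal(size=(8, 32))
        a[:, :4] += 1.2
        perm = np.random.default_rng(1).permutation(32)
        adj_p = cp.Adjacency(matrix=adjacency32.matrix[np.ix_(perm, perm)])
        cs1 = cp.permutation_test(a, b, "dependent", adjacency32, R=300, seed=5)
        cs2 = cp.permutation_test(a[:, perm], b[:, perm], "dependent", adj_p, R=300, seed=5)
        p1 = sorted(c.p for c in cs1.clusters)
        p2 = sorted(c.p for c in cs2.clusters)
        assert p1 == p2

    def test_invalid_r_rejected(self, rng, adjacency32):
        with pytest.raises(ValueError):
            cp.permutation_test(rng.normal(size=(5, 32)), rng.normal(size=(5, 32)),
                                "dependent", adjacency32, R=0)


def exact_signflip_pvalues(a, b, threshold, adjacency, min_neighbors=0):
    """Independent oracle: full 2^n enumeration of condition sign flips,
    returning the exact p of every observed cluster against the
    distribution of the maximal |T_sum|."""
    d = a - b
    n = d.shape[0]
    null = []
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        t = cp.elementwise_t(d * np.array(signs)[:, None], np.zeros_like(d), "dependent")
        cs = cp.form_clusters(t, threshold, adjacency, min_neighbors)
        null.append(max((abs(c.t_sum) for c in cs.clusters), default=0.0))
    null = np.array(null)
    observed = cp.form_clusters(
        cp.elementwise_t(a, b, "dependent"), threshold, adjacency, min_neighbors
    )
    return [(c, np.mean(null >= abs(c.t_sum) - 1e-12)) for c in observed.clusters]


class TestExactEnumerationOracle:
    def test_monte_carlo_matches_enumeration_n5(self, rng):
        """For 5 paired subjects the Monte Carlo cluster p must agree
        with the exact 2^5 sign-flip enumeration within binomial error."""
        adj = chain_adjacency(6)
        found = 0
        for trial in range(8):
            a = rng.normal(size=(5, 6))
            b = rng.normal(size=(5, 6))
            a[:, 2:4] += 1.8
            thr = float(stats.t.ppf(0.975, 4))
            exact = exact_signflip_pvalues(a, b, thr, adj)
            if not exact:
                continue
            R = 2000
            mc = cp.permutation_test(a, b, "dependent", adj, R=R, seed=trial,
                                     threshold=thr, min_neighbors=0)
            for (c_ex, p_ex), c_mc in zip(exact, mc.clusters):
                assert sorted(c_ex.nodes) == sorted(c_mc.nodes)
                tol = 3.0 * np.sqrt(p_ex * (1 - p_ex) / R) + 2.0 / R
                assert c_mc.p == pytest.approx(p_ex, abs=max(tol, 0.02))
                found += 1
        assert found >= 5  # enumeration exercised on several clusters
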