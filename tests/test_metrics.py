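"""Thresholding, graph metrics, null models, AUC, sparsity selection, hubs."""

import numpy as np
import pytest

import morphkls as mk
from morphkls.metrics import (
    DEFAULT_SPARSITIES,
    hub_scores,
    rewired_null,
    select_sparsity_range,
    small_world_indices,
    threshold_by_sparsity,
)

from . import oracles


def adj_from_edges(n, edges, weights=None):
    a = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        a[i, j] = a[j, i] = w
    return a

TRIANGLE_PENDANT = adj_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
STAR4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
K5 = adj_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


class TestThresholding:
    def test_full_sparsity_keeps_all(self, subject_network):
        g = threshold_by_sparsity(subject_network, 1.0)
        assert g.n_edges == 4005

    def test_rounding_half_even_at_010(self, subject_network):
        # 0.10 * 4005 = 400.5 -> 400 under round-half-even
        assert threshold_by_sparsity(subject_network, 0.10).n_edges == 400
        assert threshold_by_sparsity(subject_network, 0.11).n_edges == 441

    def test_keeps_strongest(self, subject_network):
        g = threshold_by_sparsity(subject_network, 0.2)
        kept = g.adjacency[np.triu_indices(90, 1)]
        dropped_max = subject_network.upper_triangle()[kept == 0].max()
        assert kept[kept > 0].min() >= dropped_max

    def test_out_of_range(self, subject_network):
        for s in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_by_sparsity(subject_network, s)

    def test_relabeling_equivariance(self, subject_network):
        rng = np.random.default_rng(0)
        perm = rng.permutation(90)
        w = subject_network.weights
        g1 = threshold_by_sparsity(w, 0.15).adjacency
        g2 = threshold_by_sparsity(w[np.ix_(perm, perm)], 0.15).adjacency
        assert np.allclose(g1[np.ix_(perm, perm)], g2)

    def test_tie_break_by_node_index(self):
        a = np.ones((4, 4)) - np.eye(4)  # all six edges tie
        g = threshold_by_sparsity(a, 0.5)  # keep 3 of 6
        iu = np.triu_indices(4, 1)
        kept = g.adjacency[iu] > 0
        assert list(kept) == [True, True, True, False, False, False]


class TestMetricExamples:
    def test_cp_binary_hand_counts(self):
        c, mean = mk.clustering_coefficient(TRIANGLE_PENDANT, "binary")
        assert np.allclose(c, [1 / 3, 1, 1, 0])
        assert mean == pytest.approx(7 / 12)
        assert mk.clustering_coefficient(K5, "binary")[1] == pytest.approx(1.0)
        assert mk.clustering_coefficient(STAR4, "binary")[1] == pytest.approx(0.0)

    def test_path_metrics_on_path3(self):
        lp, eglob, nodal = mk.path_length_and_efficiency(PATH3, "binary")
        assert lp == pytest.approx(4 / 3)
        assert eglob == pytest.approx((1 + 1 + 0.5) / 3)
        assert nodal[1] == pytest.approx(1.0)

    def test_eglob_disconnected(self):
        two = np.zeros((2, 2))
        _, eglob, _ = mk.path_length_and_efficiency(two, "binary")
        assert eglob == 0.0

    def test_weighted_equals_binary_at_unit_weights(self):
        for adj in (TRIANGLE_PENDANT, PATH3, K5):
            assert mk.path_length_and_efficiency(adj, "weighted")[0] == \
                pytest.approx(mk.path_length_and_efficiency(adj, "binary")[0])

    def test_local_efficiency_examples(self):
        k4 = adj_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert mk.local_efficiency(k4, "binary")[1] == pytest.approx(1.0)
        assert mk.local_efficiency(STAR4, "binary")[1] == pytest.approx(0.0)
        got, _ = mk.local_efficiency(TRIANGLE_PENDANT, "binary")
        assert np.allclose(got, oracles.brute_local_efficiency(TRIANGLE_PENDANT, "binary"))

    def test_betweenness_examples(self):
        assert np.allclose(mk.betweenness(PATH3, "binary"), [0, 1, 0])
        assert np.allclose(mk.betweenness(STAR4, "binary"), [3, 0, 0, 0])
        assert np.allclose(mk.betweenness(K5, "binary"), 0)

    def test_degree_examples(self):
        assert np.allclose(mk.nodal_degree(PATH3, "binary"), [1, 2, 1])
        w = adj_from_edges(3, [(0, 1), (1, 2)], [0.5, 0.25])
        assert np.allclose(mk.nodal_degree(w, "weighted"), [0.5, 0.75, 0.25])
        assert mk.nodal_degree(STAR4, "binary")[1] == 1


class TestWeightedOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_weighted_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        a = np.triu(rng.uniform(0.1, 1.0, (n, n)), 1)
        a[rng.random((n, n)) < 0.4] = 0  # sparsify
        a = a + a.T
        cw, _ = mk.clustering_coefficient(a, "weighted")
        assert np.allclose(cw, oracles.brute_clustering(a, "weighted"), atol=1e-9)
        lp, eg, ne = mk.path_length_and_efficiency(a, "weighted")
        blp, beg, bne = oracles.brute_lp_eglob_nodal(a, "weighted")
        assert lp == pytest.approx(blp, abs=1e-9)
        assert eg == pytest.approx(beg, abs=1e-9)
        assert np.allclose(ne, bne, atol=1e-9)
        assert np.allclose(mk.betweenness(a, "weighted"),
                           oracles.brute_betweenness(a, "weighted"), atol=1e-7)
        el, _ = mk.local_efficiency(a, "weighted")
        assert np.allclose(el, oracles.brute_local_efficiency(a, "weighted"),
                           atol=1e-9)


class TestNullModels:
    def test_null_preserves_degrees_edges_weights(self, subject_network):
        g = threshold_by_sparsity(subject_network, 0.12)
        deg = (g.adjacency > 0).sum(axis=1)
        weights = np.sort(g.adjacency[np.triu_indices(90, 1)])
        for seed in range(5):
            null = rewired_null(g, seed)
            assert np.array_equal((null > 0).sum(axis=1), deg)
            assert np.array_equal(np.sort(null[np.triu_indices(90, 1)]), weights)
            assert np.allclose(null, null.T)

    def test_rewiring_actually_changes_graph(self, subject_network):
        g = threshold_by_sparsity(subject_network, 0.12)
        null = rewired_null(g, 1)
        assert not np.array_equal(null > 0, g.adjacency > 0)

    def test_too_few_edges(self):
        from morphkls.metrics import ThresholdedGraph

        g = ThresholdedGraph(0.1, adj_from_edges(4, [(0, 1)]))
        with pytest.raises(ValueError, match="too few"):
            rewired_null(g, 0)

    def test_small_world_indices_identities(self):
        gamma, lam, sigma = small_world_indices(
            np.array([0.4]), np.array([2.0]), np.array([0.4]), np.array([2.0]))
        assert gamma[0] == 1 and lam[0] == 1 and sigma[0] == 1


class TestAUC:
    def test_constant_curve(self):
        s = DEFAULT_SPARSITIES
        assert mk.auc(np.full(s.size, 3.0), s) == pytest.approx(0.24 * 3.0)

    def test_linear_ramp(self):
        s = DEFAULT_SPARSITIES
        ramp = np.linspace(0, 1, s.size)
        assert mk.auc(ramp, s) == pytest.approx(0.12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mk.auc(np.array([1.0]), np.array([0.1]))

    def test_linearity(self):
        rng = np.random.default_rng(2)
        s = DEFAULT_SPARSITIES
        f, g = rng.normal(size=s.size), rng.normal(size=s.size)
        lhs = mk.auc(2.5 * f - 1.5 * g, s)
        assert lhs == pytest.approx(2.5 * mk.auc(f, s) - 1.5 * mk.auc(g, s))


class TestSparsitySelection:
    def test_degree_rule_alone(self, subject_network):
        # mean degree = 2*round(S*4005)/90 must exceed 2 ln 90 = 8.9998
        lo, hi = select_sparsity_range([subject_network], sigma_min=0)
        assert lo == pytest.approx(0.11)
        assert hi == pytest.approx(DEFAULT_SPARSITIES[-1])

    def test_empty_range_rejected(self, subject_network):
        with pytest.raises(ValueError, match="no admissible"):
            select_sparsity_range([subject_network], sigma_min=0,
                                  degree_rule=1e9)

    def test_sigma_rule_applies(self, subject_network):
        lo, hi = select_sparsity_range(
            [subject_network], sparsities=np.array([0.12, 0.13]),
            sigma_min=1.1, n_null=5, seed=0)
        assert (lo, hi) == (0.12, 0.13)  # modular KLS networks are small-world


class TestHubScores:
    def test_top9_per_metric_and_scores(self):
        rng = np.random.default_rng(3)
        base = {m: rng.random((5, 90)) for m in ("betweenness", "degree", "efficiency")}
        # node 0 forced to the top of all three metrics
        for v in base.values():
            v[:, 0] = 10.0
        df = hub_scores(base)
        assert df.loc[0, "hub_score"] == 3 and bool(df.loc[0, "is_hub"])
        for m in ("betweenness", "degree", "efficiency"):
            assert df[f"top_{m}"].sum() == 9
        assert df["hub_score"].between(0, 3).all()

    def test_tie_at_rank9_broken_by_index(self):
        vals = np.zeros((1, 90))
        vals[0, :20] = 1.0  # 20-way tie: indices 0..8 must win
        df = hub_scores({m: vals for m in ("betweenness", "degree", "efficiency")})
        assert df["hub_score"].sum() == 27
        assert set(df.index[df["hub_score"] == 3]) == set(range(9))


def test_metrics_invariant_under_node_permutation(subject_network):
    rng = np.random.default_rng(4)
    perm = rng.permutation(90)
    g = threshold_by_sparsity(subject_network.weights, 0.15).adjacency
    gp = g[np.ix_(perm, perm)]
    c1, m1 = mk.clustering_coefficient(g, "weighted")
    c2, m2 = mk.clustering_coefficient(gp, "weighted")
    assert m1 == pytest.approx(m2) and np.allclose(c1[perm], c2)
    lp1, eg1, ne1 = mk.path_length_and_efficiency(g, "weighted")
    lp2, eg2, ne2 = mk.path_length_and_efficiency(gp, "weighted")
    assert lp1 == pytest.approx(lp2) and eg1 == pytest.approx(eg2)
    assert np.allclose(ne1[perm], ne2)
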