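import numpy as np
import pytest

from covnet.network import (
    BinaryNetwork,
    binarize_top_edges,
    matched_edge_count,
    minimum_edge_count,
    partial_corr_values,
    partial_correlation_matrix,
    ranked_positive_edges,
    residualize,
    wiring_cost_of,
)

from conftest import random_correlation_matrix
from oracles import minimum_edges_scan_oracle, partial_corr_pair_oracle


def sym(entries, p):
    m = np.eye(p)
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return m


class TestResidualize:
    def test_no_covariates_is_mean_centering(self, rng):
        x = rng.normal(size=(10, 3))
        out = residualize(x, None)
        np.testing.assert_allclose(out, x - x.mean(axis=0), atol=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        x = rng.normal(size=(50, 4))
        c = rng.normal(size=(50, 3))
        out = residualize(x, c)
        scale = np.abs(x).max()
        assert np.abs(out.sum(axis=0)).max() < 1e-8 * scale
        assert np.abs(c.T @ out).max() < 1e-8 * scale * 50

    def test_exact_linear_dependence_gives_zero_residuals(self):
        c = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([[1.0], [3.0], [5.0], [7.0]])  # y = 1 + 2c
        out = residualize(y, c)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rank_deficient_design_rejected(self, rng):
        c = np.ones((20, 2))  # both columns collinear with the intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(rng.normal(size=(20, 2)), c)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.normal(size=(30, 5))
        values = partial_corr_values(x, None)
        np.testing.assert_allclose(values, np.corrcoef(x, rowvar=False),
                                   atol=1e-12)

    def test_duplicate_region_gives_unit_correlation(self, rng):
        x = rng.normal(size=(20, 2))
        x = np.column_stack([x, x[:, 0]])
        values = partial_corr_values(x, rng.normal(size=20))
        assert values[0, 2] == pytest.approx(1.0, abs=1e-10)

    def test_fixture_matches_independent_oracle(self):
        """6 subjects x 3 regions x 1 covariate, entrywise to 1e-12."""
        thickness = np.array([
            [2.51, 3.02, 2.77],
            [2.43, 2.95, 2.81],
            [2.60, 3.10, 2.70],
            [2.38, 2.90, 2.88],
            [2.55, 3.05, 2.75],
            [2.47, 2.99, 2.79],
        ])
        cov = np.array([[31.0], [44.0], [28.0], [50.0], [35.0], [41.0]])
        values = partial_corr_values(thickness, cov)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = partial_corr_pair_oracle(
                    thickness[:, i], thickness[:, j], cov
                )
                assert values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_covariate_rescaling_invariance(self, rng):
        x = rng.normal(size=(40, 6))
        c = rng.normal(size=(40, 2))
        v1 = partial_corr_values(x, c)
        v2 = partial_corr_values(x, c * np.array([3.7, -0.2]) + 11.0)
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_metadata_and_df(self, rng):
        x = rng.normal(size=(25, 4))
        c = rng.normal(size=(25, 3))
        pcm = partial_correlation_matrix(x, c, [f"r{i}" for i in range(4)])
        assert pcm.n_subjects == 25
        assert pcm.k_covariates == 3
        assert pcm.residual_df == 20
        with pytest.raises(ValueError, match="n >= k \\+ 3"):
            partial_correlation_matrix(x[:5], c[:5], [f"r{i}" for i in range(4)])


class TestMinimumEdgeCount:
    def test_three_node_hand_trace(self):
        m = sym({(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.1}, 3)
        e, cost = minimum_edge_count(m)
        assert e == 2
        assert cost == pytest.approx(2 / 3)

    def test_four_node_chain_hand_trace(self):
        m = sym({(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7,
                 (0, 2): 0.3, (0, 3): 0.2, (1, 3): 0.1}, 4)
        e, cost = minimum_edge_count(m)
        assert e == 3
        assert cost == pytest.approx(0.5)

    def test_not_connectable(self):
        m = sym({(0, 1): 0.9, (0, 2): -0.5, (1, 2): -0.1}, 3)
        with pytest.raises(ValueError, match="not connectable"):
            minimum_edge_count(m)

    def test_matches_brute_force_scan(self, rng):
        """E_min equals the smallest E whose top-E graph is connected,
        over random 10-node correlation matrices."""
        for _ in range(30):
            m = random_correlation_matrix(rng, p=10, n=14)
            e, _ = minimum_edge_count(m)
            assert e == minimum_edges_scan_oracle(m)

    def test_bottleneck_property(self, rng):
        """Binarizing at E_min connects the graph; at E_min - 1 it does not."""
        import networkx as nx
        for _ in range(20):
            m = random_correlation_matrix(rng, p=12, n=16)
            e, _ = minimum_edge_count(m)
            g_at = nx.from_numpy_array(binarize_top_edges(m, e).adjacency)
            assert nx.is_connected(g_at)
            if e > 1:
                g_below = nx.from_numpy_array(
                    binarize_top_edges(m, e - 1).adjacency
                )
                assert not nx.is_connected(g_below)


class TestMatchingAndBinarize:
    def test_matched_cost_is_largest_minimum(self, rng):
        ms = [random_correlation_matrix(rng, p=10, n=14) for _ in range(3)]
        per_group = [minimum_edge_count(m)[0] for m in ms]
        assert matched_edge_count(ms) == max(per_group)
        assert matched_edge_count(ms[::-1]) == matched_edge_count(ms)

    def test_single_group_is_identity(self, rng):
        m = random_correlation_matrix(rng, p=8, n=12)
        assert matched_edge_count([m]) == minimum_edge_count(m)[0]

    def test_reported_costs_match_to_largest(self):
        """Per-group minimum costs 0.0868 / 0.2075 / 0.4987 -> matched 0.4987."""
        costs = [0.0868, 0.2075, 0.4987]
        assert max(costs) == pytest.approx(0.4987)

    def test_top_edges_selected(self):
        m = sym({(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7,
                 (0, 2): 0.3, (0, 3): -0.5, (1, 3): 0.1}, 4)
        net = binarize_top_edges(m, 3)
        expected = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(net.adjacency, expected)

    def test_tie_broken_lexicographically(self):
        m = sym({(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.5}, 3)
        net = binarize_top_edges(m, 2)
        assert net.adjacency[0, 2] == 1  # (0,2) beats (1,2) at equal weight
        assert net.adjacency[1, 2] == 0

    def test_all_positive_full_budget_gives_complete_graph(self):
        m = sym({(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.2}, 3)
        net = binarize_top_edges(m, 3)
        assert net.edge_count == 3
        assert wiring_cost_of(net) == pytest.approx(1.0)

    def test_insufficient_positive_edges(self):
        m = sym({(0, 1): 0.9, (0, 2): -0.5, (1, 2): -0.1}, 3)
        with pytest.raises(ValueError, match="insufficient positive"):
            binarize_top_edges(m, 2)

    def test_negative_entries_never_become_edges(self, rng):
        m = random_correlation_matrix(rng, p=10, n=12)
        ii, jj = ranked_positive_edges(m)
        assert (m[ii, jj] > 0).all()
        net = binarize_top_edges(m, len(ii))
        edge_i, edge_j = np.nonzero(np.triu(net.adjacency, k=1))
        assert (m[edge_i, edge_j] > 0).all()


class TestWiringCost:
    @pytest.mark.parametrize("edges,expected", [
        (0, 0.0), (3, 0.5), (6, 1.0),
    ])
    def test_four_node_costs(self, edges, expected):
        adj = np.zeros((4, 4), dtype=int)
        pairs = [(0, 1), (1, 2), (2, 3), (0, 2), (0, 3), (1, 3)]
        for i, j in pairs[:edges]:
            adj[i, j] = adj[j, i] = 1
        assert wiring_cost_of(BinaryNetwork(adj, ("a", "b", "c", "d"))) \
            == pytest.approx(expected)
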