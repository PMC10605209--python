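"""Graph metrics: worked examples, monotonicity, small-world behavior."""

import numpy as np
import pytest

from conftest import complete_adjacency, path_adjacency, star_adjacency
from scnkit import (clustering_and_transitivity, local_efficiency,
                    metric_curve, path_length_and_efficiency, small_world,
                    sparsity_grid, threshold_over_grid)
from scnkit.metrics import (MetricCurve, betweenness, degrees,
                            rewire_degree_preserving)


def diamond() -> np.ndarray:
    """4-cycle 1-2-3-4 plus the 1-3 diagonal."""
    a = np.zeros((4, 4), dtype=np.int8)
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]:
        a[i, j] = a[j, i] = 1
    return a


class TestClustering:
    def test_triangle_and_star(self):
        _, cp, t = clustering_and_transitivity(complete_adjacency(3))
        assert cp == 1.0 and t == 1.0
        _, cp, t = clustering_and_transitivity(star_adjacency(5))
        assert cp == 0.0 and t == 0.0

    def test_diamond_by_exhaustive_count(self):
        c, cp, t = clustering_and_transitivity(diamond())
        assert np.allclose(c, [2 / 3, 1.0, 2 / 3, 1.0])
        assert cp == pytest.approx(5 / 6)
        assert t == pytest.approx(0.75)


class TestPathsAndEfficiency:
    def test_complete_graph(self):
        lp, eglob, _, frac = path_length_and_efficiency(
            complete_adjacency(6))
        assert lp == 1.0 and eglob == 1.0 and frac == 1.0

    def test_three_path_enumeration(self):
        lp, eglob, _, _ = path_length_and_efficiency(path_adjacency(3))
        assert lp == pytest.approx(4 / 3)
        assert eglob == pytest.approx(5 / 6)

    def test_empty_graph_flags_unreachable(self):
        lp, eglob, _, frac = path_length_and_efficiency(
            np.zeros((4, 4), dtype=np.int8))
        assert np.isnan(lp) and eglob == 0.0 and frac == 0.0

    def test_disconnected_reports_reachable_fraction(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        lp, _, _, frac = path_length_and_efficiency(a)
        assert lp == 1.0            # reachable pairs only
        assert frac == pytest.approx(4 / 12)


class TestLocalEfficiency:
    def test_triangle_and_star(self):
        assert local_efficiency(complete_adjacency(3))[0] == 1.0
        assert local_efficiency(star_adjacency(5))[0] == 0.0

    def test_diamond_induced_subgraphs(self):
        eloc, per = local_efficiency(diamond())
        assert np.allclose(per, [5 / 6, 1.0, 5 / 6, 1.0])
        assert eloc == pytest.approx(11 / 12)


class TestBetweenness:
    def test_middle_of_three_path(self):
        assert betweenness(path_adjacency(3))[1] == pytest.approx(1.0)

    def test_complete_graph_zero(self):
        assert np.allclose(betweenness(complete_adjacency(5)), 0.0)

    def test_star_center_routes_all_pairs(self):
        b = betweenness(star_adjacency(5))
        assert b[0] == pytest.approx(1.0)
        assert np.allclose(b[1:], 0.0)


class TestRewiring:
    def test_preserves_degree_sequence(self):
        rng = np.random.default_rng(0)
        a = (rng.random((30, 30)) < 0.2).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        null = rewire_degree_preserving(a, 10 * int(a.sum() // 2), rng)
        assert np.array_equal(null.sum(1), a.sum(1))
        assert not np.array_equal(null, a)

    def test_deterministic_given_seed(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        a = star_adjacency(8) | path_adjacency(8)
        n1 = rewire_degree_preserving(a, 50, rng1)
        n2 = rewire_degree_preserving(a, 50, rng2)
        assert np.array_equal(n1, n2)


class TestSmallWorld:
    def test_complete_graph_sigma_one_with_warning(self):
        with pytest.warns(UserWarning, match="no rewiring"):
            sw = small_world(complete_adjacency(8), n_null=5, seed=0)
        assert sw.gamma == sw.lambda_ == sw.sigma == 1.0

    def test_ring_lattice_is_small_world_relative_to_nulls(self):
        """A 60-node ring lattice (4 nearest neighbors) has clustering 0.5
        vs ~degree/N in rewired nulls, so gamma > 2 and sigma > 1."""
        n = 60
        a = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for off in (1, 2):
                j = (i + off) % n
                a[i, j] = a[j, i] = 1
        sw = small_world(a, n_null=50, seed=1)
        assert sw.gamma > 2.0
        assert sw.sigma > 1.0

    def test_null_ensemble_stability_across_seeds(self):
        """sigma estimated with two different seeds differs < 5% at
        n_null = 100 on a default synthetic graph."""
        from scnkit import SyntheticSpec, correlation_network, \
            generate_cohort, residualize, threshold_by_sparsity
        gmv, cov = generate_cohort(SyntheticSpec(), seed=2)
        res = residualize(gmv, cov)
        net = correlation_network(res.subset("HC"), "HC")
        g = threshold_by_sparsity(net, 0.33)
        s1 = small_world(g, n_null=100, seed=10).sigma
        s2 = small_world(g, n_null=100, seed=20).sigma
        assert abs(s1 - s2) / s1 < 0.05

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="at least one edge"):
            small_world(np.zeros((5, 5), dtype=np.int8))


class TestMetricCurves:
    def test_constant_curve_rectangle_auc(self):
        grid = sparsity_grid()
        curve = MetricCurve(grid, np.full(16, 2.5))
        assert curve.auc == pytest.approx(0.30 * 2.5)

    def test_linear_curve_trapezoid_auc(self):
        grid = sparsity_grid()
        vals = np.linspace(1.0, 3.0, 16)
        assert MetricCurve(grid, vals).auc == pytest.approx(0.30 * 2.0)

    def test_single_density_grid_rejected(self):
        from scnkit.netbuild import SparsityGrid
        with pytest.raises(ValueError, match="two densities"):
            MetricCurve(SparsityGrid((0.3,)), np.array([1.0]))

    def test_unknown_metric_name_rejected(self):
        from scnkit import CovarianceNetwork
        rng = np.random.default_rng(0)
        w = rng.uniform(-1, 1, (8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = CovarianceNetwork(w, tuple("abcdefgh"))
        graphs = threshold_over_grid(net, sparsity_grid(0.2, 0.4, 0.1))
        with pytest.raises(ValueError, match="unknown metric"):
            metric_curve(graphs, "no_such_metric", sparsity_grid(0.2, 0.4, 0.1))

    def test_metric_trends_along_nested_graphs(self):
        """Along the nested threshold sequence of one covariance network,
        global efficiency is exactly non-decreasing (extra edges can only
        shorten paths); clustering, transitivity and local efficiency rise
        overall (individual steps may dip: a new edge inflates a node's
        pair count faster than its triangle count)."""
        from scnkit import CovarianceNetwork
        rng = np.random.default_rng(4)
        w = rng.uniform(-1, 1, (20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = CovarianceNetwork(w, tuple(f"r{i}" for i in range(20)))
        grid = sparsity_grid()
        graphs = threshold_over_grid(net, grid)
        eglob = metric_curve(graphs, "global_efficiency", grid).values
        assert np.all(np.diff(eglob) >= -1e-12)
        for name in ("clustering", "transitivity", "local_efficiency"):
            vals = metric_curve(graphs, name, grid).values
            assert vals[-1] > vals[0], name
            assert np.mean(np.diff(vals)) > 0, name

    def test_degree_sum_is_twice_edge_count(self, default_residuals):
        from scnkit import correlation_network, threshold_by_sparsity
        net = correlation_network(default_residuals.subset("PWSD"))
        g = threshold_by_sparsity(net, 0.19)
        assert degrees(g).sum() == 2 * g.edge_count == 2 * 761
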