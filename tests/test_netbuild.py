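"""Network construction: residualization, correlation, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnkit import (CovarianceNetwork, CovariateTable, GMVTable,
                    correlation_network, residualize, sparsity_grid,
                    threshold_by_sparsity, threshold_over_grid)
from scnkit.cohort import ResidualTable
from scnkit.netbuild import edge_count_for_sparsity


def _cov(ids, age=None, sex=None, tiv=None):
    n = len(ids)
    return CovariateTable(
        ids,
        np.full(n, 30.0) if age is None else np.asarray(age, float),
        np.zeros(n) if sex is None else np.asarray(sex, float),
        np.full(n, 1400.0) if tiv is None else np.asarray(tiv, float),
    )


def _ids(n):
    return tuple(f"s{i}" for i in range(n))


class TestResidualize:
    def test_constant_covariates_give_centered_columns(self):
        values = np.array([[1.0], [2.0], [3.0], [4.0], [10.0]])
        gmv = GMVTable(values, _ids(5), ("r1",))
        with pytest.warns(UserWarning, match="constant"):
            res = residualize(gmv, _cov(_ids(5)))
        assert np.allclose(res.values, values - values.mean())

    def test_region_linear_in_age_residuals_zero(self):
        age = np.array([20.0, 25, 30, 40, 55, 60])
        values = (3.0 + 0.1 * age)[:, None]
        gmv = GMVTable(values, _ids(6), ("r1",))
        cov = _cov(_ids(6), age=age, sex=[0, 1, 0, 1, 0, 1],
                   tiv=[1300, 1350, 1400, 1450, 1500, 1550.0])
        res = residualize(gmv, cov)
        assert np.allclose(res.values, 0.0, atol=1e-10)

    def test_hand_computed_ols_slope_and_residuals(self):
        """Single region on age only: slope 105/500 = 0.21 and residuals
        (−0.10, −0.20, 0.70, −0.40), from centered cross-products."""
        gmv = GMVTable(np.array([[10.0], [12.0], [15.0], [16.0]]),
                       _ids(4), ("r1",))
        cov = _cov(_ids(4), age=[20.0, 30.0, 40.0, 50.0])
        with pytest.warns(UserWarning):
            res = residualize(gmv, cov)
        assert np.allclose(res.values.ravel(), [-0.10, -0.20, 0.70, -0.40])

    def test_columns_sum_to_zero(self, default_residuals):
        assert np.allclose(default_residuals.values.sum(axis=0), 0.0,
                           atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, small_spec):
        from scnkit import generate_cohort
        gmv, cov = generate_cohort(small_spec)
        res = residualize(gmv, cov)
        for c in (cov.age, cov.sex, cov.tiv):
            assert np.max(np.abs((c - c.mean()) @ res.values)) < 1e-7

    def test_sex_coding_cannot_change_residuals(self):
        rng = np.random.default_rng(0)
        values = rng.normal(6, 1, size=(12, 4))
        sex = (rng.random(12) < 0.5).astype(float)
        age = rng.normal(30, 5, 12)
        tiv = rng.normal(1400, 100, 12)
        gmv = GMVTable(values, _ids(12), tuple("abcd"))
        r1 = residualize(gmv, _cov(_ids(12), age, sex, tiv))
        r2 = residualize(gmv, _cov(_ids(12), age, 1.0 - sex, tiv))
        assert np.allclose(r1.values, r2.values, atol=1e-10)

    def test_mismatched_ids_error(self):
        gmv = GMVTable(np.ones((5, 1)) * np.arange(5)[:, None],
                       _ids(5), ("r1",))
        with pytest.raises(ValueError, match="missing"):
            residualize(gmv, _cov(tuple(f"x{i}" for i in range(5))))


def _res_table(values):
    values = np.asarray(values, float)
    return ResidualTable(values - values.mean(axis=0),
                         _ids(values.shape[0]),
                         tuple(f"r{j}" for j in range(values.shape[1])))


class TestCorrelationNetwork:
    def test_identical_and_reversed_columns(self):
        net = correlation_network(_res_table(
            np.array([[1.0, 1.0, 3.0], [2.0, 2.0, 2.0], [3.0, 3.0, 1.0]])))
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(net.weights), 0.0)

    def test_hand_computed_pearson(self):
        net = correlation_network(_res_table(
            np.array([[1.0, 1.0], [2.0, 3.0], [4.0, 3.0]])))
        assert net.weights[0, 1] == pytest.approx(24 / np.sqrt(1008))

    def test_fewer_than_three_subjects_error(self):
        with pytest.raises(ValueError, match="3 subjects"):
            correlation_network(_res_table(np.ones((2, 3))))

    def test_zero_variance_column_warns_and_zeroes(self):
        values = np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]])
        t = ResidualTable(values, _ids(3), ("a", "b"))
        with pytest.warns(UserWarning, match="zero-variance"):
            net = correlation_network(t)
        assert net.weights[0, 1] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 5))
        n1 = correlation_network(_res_table(values))
        scaled = values.copy()
        scaled[:, 2] = scaled[:, 2] * 7.5 - 3.0
        n2 = correlation_network(_res_table(scaled))
        assert np.allclose(n1.weights, n2.weights, atol=1e-12)


def _random_network(n, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return CovarianceNetwork(w, tuple(f"r{i}" for i in range(n)))


class TestThreshold:
    def test_aal90_edge_counts(self):
        net = _random_network(90)
        assert threshold_by_sparsity(net, 0.19).edge_count == 761
        assert threshold_by_sparsity(net, 1.0).edge_count == 4005

    def test_four_node_top_half(self):
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.5, (0, 3): 0.8,
                (1, 2): 0.1, (1, 3): 0.7, (2, 3): 0.3}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        g = threshold_by_sparsity(
            CovarianceNetwork(w, ("a", "b", "c", "d")), 0.5)
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency)))}
        assert kept == {(0, 1), (0, 3), (1, 3)}

    def test_signed_vs_absolute_ranking(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.95
        w[0, 2] = w[2, 0] = 0.2
        w[1, 2] = w[2, 1] = 0.1
        net = CovarianceNetwork(w, ("a", "b", "c"))
        g_signed = threshold_by_sparsity(net, 1 / 3, ranking="signed")
        g_abs = threshold_by_sparsity(net, 1 / 3, ranking="absolute")
        assert g_signed.adjacency[0, 2] == 1
        assert g_abs.adjacency[0, 1] == 1

    def test_invalid_sparsity(self):
        net = _random_network(5)
        for s in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_by_sparsity(net, s)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_nested_edge_sets_across_grid(self, seed):
        """Edge sets are monotone along the density grid."""
        net = _random_network(12, seed=seed)
        graphs = threshold_over_grid(net, sparsity_grid(0.1, 0.9, 0.2))
        for g1, g2 in zip(graphs, graphs[1:]):
            assert np.all(g2.adjacency >= g1.adjacency)

    def test_grid_and_single_density_agree(self):
        net = _random_network(20, seed=3)
        grid = sparsity_grid()
        for g_grid, s in zip(threshold_over_grid(net, grid), grid):
            single = threshold_by_sparsity(net, s)
            assert np.array_equal(g_grid.adjacency, single.adjacency)

    def test_rounding_half_away_from_zero(self):
        # 0.5 * 5 choose 2 = 5.0 exactly; 0.45 * 10 = 4.5 -> 5
        assert edge_count_for_sparsity(0.5, 5) == 5
        assert edge_count_for_sparsity(0.45, 5) == 5


class TestSparsityGrid:
    def test_default_grid_matches_protocol(self):
        grid = sparsity_grid()
        assert len(grid) == 16
        assert grid.values[0] == 0.19
        assert grid.values[-1] == 0.49
        assert np.allclose(np.diff(grid.as_array()), 0.02)
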