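"""Residualization, correlation networks and density thresholding."""

import numpy as np
import pytest

import thalnet as tn
from thalnet.labels import NUCLEUS_COLUMNS
from thalnet.network import (
    GroupNetwork,
    ResidualTable,
    UndefinedCorrelationError,
    edge_count_at_density,
    ranked_pairs,
)


class TestResidualize:
    def test_empty_covariates_mean_centers(self, small_cohort):
        res = tn.residualize(small_cohort, "HC", covariates=())
        V = small_cohort.volumes("HC")
        np.testing.assert_allclose(res.residuals, V - V.mean(axis=0),
                                   atol=1e-12)

    def test_perfect_linear_fit_leaves_zero(self, small_cohort):
        df = small_cohort.data.copy()
        for c in NUCLEUS_COLUMNS:
            df[c] = 1.0 + 0.01 * df["age"]
        cohort = tn.CohortTable(df)
        res = tn.residualize(cohort, "HC", covariates=("age",))
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-8)

    def test_matches_least_squares_oracle(self, default_cohort):
        res = tn.residualize(default_cohort, "F-MS",
                             covariates=("age", "sex", "lesion_volume"))
        sub = default_cohort.subset(["F-MS"])
        V = sub.volumes()
        X = np.column_stack([np.ones(len(sub)),
                             sub.covariate_matrix(("age", "sex", "lesion_volume"))])
        beta, *_ = np.linalg.lstsq(X, V, rcond=None)
        np.testing.assert_allclose(res.residuals, V - X @ beta, atol=1e-8)

    def test_residual_columns_centered_and_orthogonal(self, default_cohort):
        res = tn.residualize(default_cohort, "NF-MS")
        assert np.all(np.abs(res.residuals.mean(axis=0)) < 1e-8)
        sub = default_cohort.subset(["NF-MS"])
        for name in res.covariates_used:
            cov = sub.data[name].to_numpy(dtype=float)
            inner = res.residuals.T @ cov
            assert np.all(np.abs(inner) < 1e-6 * max(1.0, np.abs(cov).sum()))

    def test_constant_covariate_dropped_in_controls(self, default_cohort):
        res = tn.residualize(default_cohort, "HC")
        assert "lesion_volume" in res.covariates_dropped
        assert "age" in res.covariates_used

    def test_too_few_subjects_rejected(self, default_cohort):
        tiny = tn.CohortTable(default_cohort.data.iloc[:3].copy())
        with pytest.raises(ValueError, match="subjects"):
            tn.residualize(tiny, "F-MS")


class TestCorrelationMatrix:
    def _residual_table(self, R: np.ndarray) -> ResidualTable:
        labels = NUCLEUS_COLUMNS[: R.shape[1]]
        return ResidualTable(group="HC", labels=labels, residuals=R,
                             covariates_used=(), covariates_dropped=())

    def test_identical_columns_correlate_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        R = np.column_stack([x, x, rng.standard_normal(10)])
        net = tn.build_correlation_matrix(self._residual_table(R))
        assert net.matrix[0, 1] == pytest.approx(1.0)
        assert net.matrix[0, 0] == 0.0

    def test_matches_hand_expanded_formula(self):
        rng = np.random.default_rng(1)
        R = rng.standard_normal((5, 3))
        net = tn.build_correlation_matrix(self._residual_table(R))
        for i in range(3):
            for j in range(i + 1, 3):
                x, y = R[:, i], R[:, j]
                n = len(x)
                num = n * (x * y).sum() - x.sum() * y.sum()
                den = np.sqrt(n * (x ** 2).sum() - x.sum() ** 2) * \
                    np.sqrt(n * (y ** 2).sum() - y.sum() ** 2)
                assert net.matrix[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_independent_columns_decorrelate_at_large_n(self):
        rng = np.random.default_rng(2)
        R = rng.standard_normal((10_000, 6))
        net = tn.build_correlation_matrix(self._residual_table(R))
        off = net.matrix[np.triu_indices(6, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_column_names_region(self):
        R = np.ones((6, 3))
        R[:, 1] = np.arange(6.0)
        R[:, 2] = np.arange(6.0) ** 2
        with pytest.raises(UndefinedCorrelationError, match="Left-AV"):
            tn.build_correlation_matrix(self._residual_table(R))

    def test_full_partial_approaches_pearson_for_two_regions(self):
        # with 2 regions partial == marginal correlation; shrinkage vanishes
        # as n grows, so the modes must agree at large n
        rng = np.random.default_rng(3)
        z = rng.standard_normal(4000)
        R = np.column_stack([z + 0.5 * rng.standard_normal(4000),
                             z + 0.5 * rng.standard_normal(4000)])
        tab = self._residual_table(R)
        pearson = tn.build_correlation_matrix(tab, mode="residual_pearson")
        partial = tn.build_correlation_matrix(tab, mode="full_partial")
        assert partial.matrix[0, 1] == pytest.approx(pearson.matrix[0, 1],
                                                     abs=0.01)

    def test_symmetry_and_range(self, default_cohort):
        net = tn.build_correlation_matrix(tn.residualize(default_cohort, "HC"))
        np.testing.assert_array_equal(net.matrix, net.matrix.T)
        assert np.all(np.abs(net.matrix) <= 1.0)
        assert np.all(np.diag(net.matrix) == 0.0)


class TestDensityGrid:
    def test_default_grid_has_36_inclusive_points(self):
        grid = tn.density_grid(tn.RunConfig())
        assert len(grid) == 36
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(0.40)
        np.testing.assert_allclose(np.diff(grid), 0.01)

    def test_degenerate_single_point(self):
        grid = tn.density_grid(sparsity_min=0.2, sparsity_max=0.2,
                               sparsity_step=0.01)
        np.testing.assert_allclose(grid, [0.2])

    def test_non_dividing_step_truncates(self):
        grid = tn.density_grid(sparsity_min=0.05, sparsity_max=0.40,
                               sparsity_step=0.15)
        np.testing.assert_allclose(grid, [0.05, 0.20, 0.35])


class TestBinarize:
    def _network(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        C = np.corrcoef(rng.standard_normal((30, n)), rowvar=False)
        np.fill_diagonal(C, 0.0)
        return GroupNetwork(group="HC", labels=NUCLEUS_COLUMNS[:n], matrix=C)

    def test_exact_edge_counts_on_fifty_nodes(self):
        net = self._network()
        assert tn.binarize_at_density(net, 0.40).n_edges == 490
        assert tn.binarize_at_density(net, 0.05).n_edges == 61
        assert edge_count_at_density(0.40, 50) == 490
        assert edge_count_at_density(0.05, 50) == 61

    def test_top_k_matches_exhaustive_sort(self):
        net = self._network(seed=1, n=12)
        A = tn.binarize_at_density(net, 0.3).matrix
        iu, ju = np.triu_indices(12, 1)
        vals = np.abs(net.matrix[iu, ju])
        assert len(np.unique(vals)) == len(vals)  # all distinct
        k = edge_count_at_density(0.3, 12)
        top = set()
        for idx in np.argsort(vals)[::-1][:k]:
            top.add((iu[idx], ju[idx]))
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(A, 1)))}
        assert got == top

    def test_edge_sets_nested_across_grid(self):
        net = self._network(seed=2)
        prev = None
        for d in tn.density_grid(tn.RunConfig()):
            A = tn.binarize_at_density(net, d).matrix
            if prev is not None:
                assert np.all(A[prev])  # every earlier edge still present
            prev = A

    def test_invariant_to_monotone_transform(self):
        net = self._network(seed=3)
        transformed = GroupNetwork(
            group="HC", labels=net.labels,
            matrix=np.sign(net.matrix) * np.abs(net.matrix) ** 3)
        for d in (0.05, 0.2, 0.4):
            a = tn.binarize_at_density(net, d).matrix
            b = tn.binarize_at_density(transformed, d).matrix
            np.testing.assert_array_equal(a, b)

    def test_degenerate_empty_graph_rejected(self):
        net = self._network(n=6)
        with pytest.raises(ValueError, match="empty"):
            tn.binarize_at_density(net, 0.01)

    def test_tie_break_is_lexicographic_and_deterministic(self):
        C = np.zeros((4, 4))
        C[0, 1] = C[1, 0] = 0.5
        C[0, 2] = C[2, 0] = 0.5
        C[0, 3] = C[3, 0] = 0.5
        net = GroupNetwork(group="HC", labels=NUCLEUS_COLUMNS[:4], matrix=C)
        A = tn.binarize_at_density(net, 2 / 6 + 1e-9).matrix  # k = 2
        assert A[0, 1] and A[0, 2] and not A[0, 3]
        ei, ej = ranked_pairs(C)
        assert (ei[0], ej[0]) == (0, 1) and (ei[1], ej[1]) == (0, 2)
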