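import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import phyloyawn as py
from phyloyawn.exceptions import (
    CollinearityError,
    DegenerateDataError,
    DomainError,
    InputError,
)
from phyloyawn.phylo_core import (
    chol_with_jitter,
    estimate_lambda,
    lambda_transform,
    pgls_fit,
    phylo_correlation,
    phylo_cov,
    vif,
)


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick")


def star_tree(n, height=1.0):
    return _tree("(" + ",".join(f"t{i}:{height}" for i in range(n)) + ");")


THREE_TAXON = "((A:1,B:1):1,C:2);"


class TestPhyloCov:
    def test_three_taxon_by_inspection(self):
        cov = phylo_cov(_tree(THREE_TAXON))
        assert cov.tip_order == ["A", "B", "C"]
        np.testing.assert_allclose(cov.matrix,
                                   [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_three_taxon_scaled(self):
        cov = phylo_cov(_tree(THREE_TAXON), scale_to_unit_height=True)
        np.testing.assert_allclose(cov.matrix,
                                   [[1, .5, 0], [.5, 1, 0], [0, 0, 1]])

    def test_matches_patristic_identity_oracle(self):
        # independent route: depth(mrca) = (d_i + d_j - patristic_ij) / 2
        tree = py.simulate_tree(20, 1.0, seed=3)
        C = phylo_cov(tree).matrix
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = list(tree.leaf_node_iter())
        pdm = tree.phylogenetic_distance_matrix()
        for i, j in itertools.combinations(range(20), 2):
            d = 0.5 * (leaves[i].root_distance + leaves[j].root_distance
                       - pdm.patristic_distance(leaves[i].taxon,
                                                leaves[j].taxon))
            assert C[i, j] == pytest.approx(d, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_semidefinite(self, seed):
        tree = py.simulate_tree(15, 1.0, seed=seed)
        C = phylo_cov(tree).matrix
        assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_negative_branch_length_rejected(self):
        with pytest.raises(InputError):
            phylo_cov(_tree("((A:1,B:-1):1,C:2);"))

    def test_explicitly_unrooted_tree_rejected(self):
        with pytest.raises(InputError, match="unrooted"):
            phylo_cov(_tree("[&U](A:1,B:1,C:1);"))

    def test_star_tree_covariance_is_diagonal(self):
        C = phylo_cov(star_tree(4, height=2.0)).matrix
        np.testing.assert_allclose(C, 2.0 * np.eye(4))


class TestLambdaTransform:
    def test_identity_at_one(self):
        C = phylo_cov(_tree(THREE_TAXON)).matrix
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)

    def test_star_at_zero(self):
        C = phylo_cov(_tree(THREE_TAXON)).matrix
        np.testing.assert_allclose(lambda_transform(C, 0.0), np.diag([2., 2., 2.]))

    def test_half(self):
        C = phylo_cov(_tree(THREE_TAXON)).matrix
        np.testing.assert_allclose(lambda_transform(C, 0.5),
                                   [[2, .5, 0], [.5, 2, 0], [0, 0, 2]])

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain(self, lam):
        with pytest.raises(DomainError):
            lambda_transform(np.eye(3), lam)


class TestEstimateLambda:
    def test_matches_dense_grid_search(self):
        tree = py.simulate_tree(50, 1.0, seed=4)
        C = phylo_cov(tree, scale_to_unit_height=True).matrix
        L = chol_with_jitter(C + 1e-12 * np.eye(50))
        rng = np.random.default_rng(0)
        for y in (L @ rng.standard_normal(50),              # strong signal
                  rng.standard_normal(50),                  # no signal
                  L @ rng.standard_normal(50) * 0.5 + rng.standard_normal(50)):
            est = estimate_lambda(y, tree)
            grid = np.linspace(0, 1, 101)
            lam_grid = grid[np.argmax([est.loglik(l) for l in grid])]
            assert abs(est.lambda_hat - lam_grid) <= 0.01
            assert est.max_loglik >= max(est.loglik(l) for l in grid) - 1e-6

    def test_constant_trait_rejected(self):
        tree = py.simulate_tree(10, 1.0, seed=1)
        with pytest.raises(DegenerateDataError):
            estimate_lambda(np.ones(10), tree)


class TestPgls:
    def test_star_tree_reduces_to_ols(self):
        n = 20
        tree = star_tree(n)
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 1.0 + 0.5 * X[:, 1] + rng.standard_normal(n)
        fit = pgls_fit(y, X, tree, lambda_mode=1.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, ols, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_exact_linear_system_has_zero_residuals(self, lam):
        tree = py.simulate_tree(12, 1.0, seed=5)
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        y = X @ np.array([2.0, -1.5])
        fit = pgls_fit(y, X, tree, lambda_mode=lam)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.coefficients, [2.0, -1.5], atol=1e-8)

    def test_three_taxon_matches_direct_matrix_formula(self):
        tree = _tree(THREE_TAXON)
        y = np.array([1.0, 2.0, 4.0])
        X = np.ones((3, 1))
        fit = pgls_fit(y, X, tree, lambda_mode=1.0)
        C = phylo_cov(tree, scale_to_unit_height=True).matrix
        Ci = np.linalg.inv(C)  # explicit inverse: independent route
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert fit.coefficients[0] == pytest.approx(beta[0], abs=1e-10)

    def test_lambda_zero_equals_weighted_least_squares(self):
        tree = py.simulate_tree(15, 1.0, seed=6)
        C = phylo_cov(tree, scale_to_unit_height=True).matrix
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(15), rng.standard_normal(15)])
        y = rng.standard_normal(15)
        fit = pgls_fit(y, X, tree, lambda_mode=0.0)
        w = 1.0 / np.diag(C)
        W = np.diag(w)
        beta_wls = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(fit.coefficients, beta_wls, atol=1e-8)

    def test_ml_lambda_agrees_with_estimate_lambda(self):
        tree = py.simulate_tree(40, 1.0, seed=7)
        C = phylo_cov(tree, scale_to_unit_height=True).matrix
        L = chol_with_jitter(C + 1e-12 * np.eye(40))
        rng = np.random.default_rng(5)
        y = L @ rng.standard_normal(40) + 0.3 * rng.standard_normal(40)
        est = estimate_lambda(y, tree)
        fit = pgls_fit(y, np.ones((40, 1)), tree, lambda_mode="ml")
        assert fit.lambda_used == pytest.approx(est.lambda_hat, abs=1e-4)

    def test_rank_deficiency_names_columns(self):
        tree = py.simulate_tree(10, 1.0, seed=8)
        rng = np.random.default_rng(6)
        x = rng.standard_normal(10)
        X = pd.DataFrame({"intercept": np.ones(10), "x": x, "x_copy": x})
        with pytest.raises(CollinearityError) as exc:
            pgls_fit(rng.standard_normal(10), X, tree)
        assert exc.value.columns


class TestPhyloCorrelation:
    def test_perfect_correlations(self):
        tree = py.simulate_tree(10, 1.0, seed=9)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10)
        assert phylo_correlation(x, x, tree) == pytest.approx(1.0)
        assert phylo_correlation(x, -2 * x + 3, tree) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        tree = py.simulate_tree(10, 1.0, seed=9)
        with pytest.raises(DegenerateDataError):
            phylo_correlation(np.ones(10), np.arange(10.0), tree)

    def test_recovery_of_generative_correlation(self):
        # bivariate Brownian simulation with true correlation 0.9
        hits = 0
        off = 0.9 * math.sqrt(2.0)
        evo = np.array([[2.0, off], [off, 1.0]])
        for s in range(20):
            tree = py.simulate_tree(200, 1.0, seed=300 + s)
            traits = py.simulate_bm_traits(tree, (0.0, 0.0), evo, seed=400 + s)
            r = phylo_correlation(traits.iloc[:, 0], traits.iloc[:, 1], tree)
            hits += abs(r - 0.9) <= 0.05
        assert hits >= 18


class TestVif:
    def test_orthogonal_columns_give_unity(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / n),
                             np.sin(2 * np.pi * t / n),
                             np.cos(4 * np.pi * t / n)])
        np.testing.assert_allclose(vif(X), 1.0, atol=1e-10)

    def test_closed_form_for_two_correlated_predictors(self):
        # exact sample correlation 0.6 by construction
        n = 100
        rng = np.random.default_rng(8)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - a * (a @ b) / (a @ a)
        b = (b - b.mean()) / b.std(ddof=1)
        X = np.column_stack([a, 0.6 * a + math.sqrt(1 - 0.36) * b])
        np.testing.assert_allclose(vif(X), 1.0 / (1.0 - 0.36), rtol=1e-6)

    def test_matches_per_column_regression_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 5))
        X[:, 4] = X[:, 0] * 0.8 + 0.2 * X[:, 4]
        expected = []
        for j in range(5):
            r2 = sm.OLS(X[:, j],
                        sm.add_constant(np.delete(X, j, axis=1))).fit().rsquared
            expected.append(1.0 / (1.0 - r2))
        np.testing.assert_allclose(vif(X), expected, rtol=1e-8)

    def test_perfect_collinearity_reported_as_inf(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x, rng.standard_normal(30)])
        v = vif(X)
        assert np.isinf(v[0]) and np.isinf(v[1]) and np.isfinite(v[2])

    def test_requires_two_columns(self):
        with pytest.raises(InputError):
            vif(np.ones((10, 1)))
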