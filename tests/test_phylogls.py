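"""Phylogenetic GLS: transforms, covariance builders, estimation, selection."""

import numpy as np
import pytest

from devallometry import synthgen
from devallometry.datamodel import read_newick
from devallometry.phylogls import (
    CorrelationStructure,
    bm_covariance,
    cov2corr,
    design_with_intercept,
    fit_candidates,
    gls_fit,
    grafen_transform,
    optimize_alpha_reml,
    ou_correlation,
    patristic_matrix,
    pgls_r2,
    reml_loglik,
    select_structure,
    structure_matrix,
    tip_labels,
    unit_branches,
)


def _depths(tree):
    out = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        out[node] = 0.0 if parent is None else out[parent] + (node.edge.length or 0.0)
    return out


class TestGrafen:
    def test_two_tip_tree(self):
        t = grafen_transform(read_newick("(A,B);"))
        depths = _depths(t)
        leaf_depths = [d for n, d in depths.items() if n.is_leaf()]
        assert leaf_depths == pytest.approx([1.0, 1.0])

    def test_balanced_four_tip_hand_values(self):
        t = grafen_transform(read_newick("((A,B),(C,D));"))
        V, labels = bm_covariance(t)
        # cherry nodes at height 1/3 -> shared depth root->cherry = 2/3
        assert V[labels.index("A"), labels.index("B")] == pytest.approx(2 / 3)
        assert np.diag(V) == pytest.approx(np.ones(4))

    def test_random_trees_nonnegative_branches_unit_height(self):
        for seed in range(50):
            tree = synthgen.simulate_tree(4 + seed % 30, seed=seed, n_clades=1 + seed % 3)
            g = grafen_transform(tree)
            for node in g.preorder_node_iter():
                if node.parent_node is not None:
                    assert node.edge.length >= 0
            depths = _depths(g)
            for node in g.leaf_node_iter():
                assert depths[node] == pytest.approx(1.0)


class TestCovarianceBuilders:
    def test_star_tree_has_no_shared_history(self):
        V, _ = bm_covariance(read_newick("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(V, np.eye(4))

    def test_hand_computed_path_sums(self):
        V, labels = bm_covariance(read_newick("((A:1,B:1):1,C:2);"))
        i = {l: k for k, l in enumerate(labels)}
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)
        assert V[i["A"], i["A"]] == pytest.approx(2.0)

    def test_matches_path_enumeration_oracle_on_random_trees(self):
        for seed in range(20):
            tree = synthgen.simulate_tree(8, seed=100 + seed, unit_branch_lengths=False)
            V, labels = bm_covariance(tree)
            # oracle: explicit root-path intersection per tip pair
            paths = {}
            for leaf in tree.leaf_node_iter():
                edges = []
                node = leaf
                while node.parent_node is not None:
                    edges.append((id(node), node.edge.length))
                    node = node.parent_node
                paths[leaf.taxon.label] = dict(edges)
            for a in range(8):
                for b in range(8):
                    shared = set(paths[labels[a]]) & set(paths[labels[b]])
                    expect = sum(paths[labels[a]][e] for e in shared)
                    assert V[a, b] == pytest.approx(expect, rel=1e-12)

    def test_ou_diagonal_is_one_and_offdiag_exact(self):
        tree = unit_branches(read_newick("((A,B),C);"))
        C, labels = ou_correlation(tree, alpha=0.5)
        assert np.diag(C) == pytest.approx(np.ones(3))
        i = {l: k for k, l in enumerate(labels)}
        assert C[i["A"], i["B"]] == pytest.approx(np.exp(-1.0))  # d_AB = 2

    def test_ou_alpha_must_be_positive(self):
        tree = unit_branches(read_newick("((A,B),C);"))
        with pytest.raises(ValueError):
            ou_correlation(tree, alpha=0.0)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            bm_covariance(read_newick("((A:1,B:-1):1,C:2);"))

    def test_grafen_bm_positive_definite_on_random_trees(self):
        for seed in range(100):
            tree = synthgen.simulate_tree(2 + seed % 40, seed=seed)
            V, _ = bm_covariance(grafen_transform(tree))
            np.linalg.cholesky(V + 0 * np.eye(len(V)))  # raises if not PD


class TestGLS:
    def test_identity_correlation_reproduces_ols(self, rng):
        x = rng.normal(size=25)
        y = 1 + 0.5 * x + rng.normal(size=25)
        X, names = design_with_intercept(x)
        gls = gls_fit(X, y, np.eye(25), names)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert gls.coefficients == pytest.approx(beta, rel=1e-12)

    def test_three_tip_explicit_dense_oracle(self, rng):
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.3, 1.1, 2.2])
        X, names = design_with_intercept(x)
        gls = gls_fit(X, y, V, names)
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        assert gls.coefficients == pytest.approx(beta, rel=1e-12)

    def test_scaling_v_leaves_coefficients_unchanged(self, rng):
        n = 15
        tree = synthgen.simulate_tree(n, seed=3)
        V, labels = bm_covariance(tree)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X, names = design_with_intercept(x)
        f1 = gls_fit(X, y, V, names)
        f2 = gls_fit(X, y, 7.3 * V, names)
        assert f1.coefficients == pytest.approx(f2.coefficients, rel=1e-10)

    def test_large_alpha_ou_converges_to_ols(self, rng):
        n = 20
        tree = synthgen.simulate_tree(n, seed=5)
        C, labels = ou_correlation(unit_branches(tree), alpha=50.0)
        x = rng.normal(size=n)
        y = 1 + 0.3 * x + rng.normal(size=n)
        X, names = design_with_intercept(x)
        gls = gls_fit(X, y, C, names)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert gls.coefficients == pytest.approx(beta, abs=1e-8)

    def test_rank_deficient_design_lists_aliased_columns(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="aliased columns"):
            gls_fit(X, rng.normal(size=10), np.eye(10), ["intercept", "x", "dup"])

    def test_whitened_residual_variance_matches_sigma2(self, rng):
        # diagnostic: residuals whitened by the true V are homoskedastic
        n = 200
        tree = synthgen.simulate_tree(n, seed=9)
        V, labels = bm_covariance(tree)
        C = cov2corr(V)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + 0.7 * (L @ rng.standard_normal(n))
        X, names = design_with_intercept(x)
        fit = gls_fit(X, y, C, names)
        assert fit.sigma2 == pytest.approx(0.49, rel=0.35)


class TestAlphaOptimization:
    def test_grid_brackets_optimizer_answer(self, rng):
        n = 60
        tree = synthgen.simulate_tree(n, seed=2, unit_branch_lengths=False)
        labels = tip_labels(tree)
        D, _ = patristic_matrix(tree, labels)
        C = np.exp(-0.8 * D)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        x = rng.normal(size=n)
        y = 1 + 0.4 * x + L @ rng.standard_normal(n)
        X, names = design_with_intercept(x)
        alpha, reml, _ = optimize_alpha_reml(tree, X, y, transform="none", labels=labels)
        grid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 50))
        vals = []
        for a in grid:
            Ca = np.exp(-a * D)
            np.fill_diagonal(Ca, 1.0)
            vals.append(reml_loglik(X, y, Ca))
        assert reml >= max(vals) - 1e-6

    def test_flat_likelihood_on_star_tree_hits_bound(self, rng):
        # a star tree induces equicorrelation exp(-2*alpha); residuals with
        # negative sample equicorrelation push alpha to the independence bound
        n = 30
        tree = read_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
        x = rng.normal(size=n)
        y = np.tile([1.0, -1.0], n // 2) + 0.01 * rng.normal(size=n)
        X, names = design_with_intercept(x)
        _, _, bound_hit = optimize_alpha_reml(tree, X, y, transform="none")
        assert bound_hit


class TestSelection:
    @staticmethod
    def _fit_with_aic(aic, rng):
        x = np.arange(5.0)
        y = np.array([0.1, 1.2, 1.9, 3.1, 4.0])
        X, names = design_with_intercept(x)
        f = gls_fit(X, y, np.eye(5), names)
        f.aic = aic
        return f

    def test_lowest_aic_selected(self, rng):
        fits = [self._fit_with_aic(a, rng) for a in (461.3, 468.1, 506.9, 627.6)]
        assert select_structure(fits) is fits[0]

    def test_single_candidate_returned(self, rng):
        f = self._fit_with_aic(100.0, rng)
        assert select_structure([f]) is f

    def test_tie_breaks_to_list_order(self, rng):
        fits = [self._fit_with_aic(100.0, rng), self._fit_with_aic(100.0, rng)]
        assert select_structure(fits) is fits[0]

    def test_differing_data_rejected(self, rng):
        f1 = self._fit_with_aic(1.0, rng)
        f2 = self._fit_with_aic(2.0, rng)
        f2.data_key = (5, 0.0, 1.0)
        with pytest.raises(ValueError, match="differing data"):
            select_structure([f1, f2])


class TestPglsR2:
    def test_full_equals_null_gives_zero(self, rng):
        x = rng.normal(size=10)
        X0 = np.ones((10, 1))
        y = rng.normal(size=10)
        null = gls_fit(X0, y, np.eye(10), ["intercept"])
        assert pgls_r2(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_identity_limit_approaches_classical_r2(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + rng.normal(size=n)
        X, names = design_with_intercept(x)
        full = gls_fit(X, y, np.eye(n), names)
        null = gls_fit(np.ones((n, 1)), y, np.eye(n), ["intercept"])
        classical = 1 - full.rss_whitened / null.rss_whitened
        assert pgls_r2(full, null) == pytest.approx(classical, abs=0.02)

    def test_mismatched_structure_rejected(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        X, names = design_with_intercept(x)
        s1 = CorrelationStructure("BM", "unit_branches")
        s2 = CorrelationStructure("OU", "unit_branches", alpha=1.0)
        f1 = gls_fit(X, y, np.eye(8), names, s1)
        f2 = gls_fit(np.ones((8, 1)), y, np.eye(8), ["intercept"], s2)
        with pytest.raises(ValueError, match="structures"):
            pgls_r2(f1, f2)
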