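"""Phylogenetic comparative machinery: covariance, λ, PGLS, ancestral states."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from camtraits.errors import OrphanTaxonError
from camtraits.phylo import (
    ancestral_states,
    bm_covariance,
    bm_loglik,
    bm_loglik_pruning,
    fit_lambda,
    lambda_transform,
    lambda_upper_bound,
    leaf_labels,
    pgls,
    prune_and_lump,
)
from camtraits.simulate import simulate_bm_traits, simulate_tree

from conftest import tree_from_newick


class TestBmCovariance:
    def test_three_tip_hand_derivation(self, three_tip_tree):
        labels, C = bm_covariance(three_tip_tree)
        i = {l: k for k, l in enumerate(labels)}
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["A"]] == pytest.approx(2.0)
        assert C[i["A"], i["C"]] == 0.0
        assert C[i["C"], i["C"]] == pytest.approx(2.0)

    def test_star_tree_is_diagonal(self, star_tree):
        _, C = bm_covariance(star_tree)
        assert np.allclose(C, np.eye(5))

    def test_symmetric_and_diagonally_dominant(self):
        tree = simulate_tree(20, seed=7)
        _, C = bm_covariance(tree)
        assert np.allclose(C, C.T)
        assert np.all(np.diag(C)[:, None] >= C - 1e-12)


class TestLambdaTransform:
    def test_identity_at_one(self, three_tip_tree):
        _, C = bm_covariance(three_tip_tree)
        assert np.allclose(lambda_transform(C, 1.0), C)

    def test_diagonal_at_zero(self, three_tip_tree):
        _, C = bm_covariance(three_tip_tree)
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_half_scales_off_diagonal(self, three_tip_tree):
        _, C = bm_covariance(three_tip_tree)
        V = lambda_transform(C, 0.5)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(V[off], 0.5 * C[off])

    def test_upper_bound_capped_for_ultrametric(self):
        tree = simulate_tree(15, seed=8)
        _, C = bm_covariance(tree)
        assert lambda_upper_bound(C) == pytest.approx(1.0)


class TestBmLoglik:
    def test_standard_normal_mode(self):
        ll = bm_loglik(np.array([0.3]), np.array([[1.0]]), mu=0.3, sigma2=1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_translation_invariance(self, five_tip_tree):
        _, C = bm_covariance(five_tip_tree)
        x = np.array([1.0, 2.0, 0.5, -1.0, 0.0])
        ll1 = bm_loglik(x, C, 0.2, 1.5)
        ll2 = bm_loglik(x + 7.0, C, 7.2, 1.5)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("lam", [1.0, 0.6, 0.0])
    def test_dense_and_pruning_agree(self, seed, lam):
        """Two independent algorithms for the same likelihood, to 1e-8."""
        tree = simulate_tree(10, seed=seed)
        labels, x = simulate_bm_traits(tree, sigma2=2.0, root=1.0, seed=seed + 50)
        _, C = bm_covariance(tree)
        dense = bm_loglik(x, lambda_transform(C, lam), mu=0.7, sigma2=1.3)
        pruned = bm_loglik_pruning(
            tree, dict(zip(labels, x)), mu=0.7, sigma2=1.3, lam=lam
        )
        assert pruned == pytest.approx(dense, abs=1e-8)


class TestFitLambda:
    def test_bm_signal_detected(self):
        tree = simulate_tree(100, seed=21)
        _, x = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=22)
        fit = fit_lambda(x, tree)
        assert fit.lam > 0.85
        assert fit.pvalue < 0.01

    def test_shuffling_destroys_signal(self):
        tree = simulate_tree(100, seed=23)
        _, x = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=24)
        rng = np.random.default_rng(25)
        fit = fit_lambda(rng.permutation(x), tree)
        assert fit.lam < 0.35

    def test_star_tree_not_identifiable(self, star_tree):
        fit = fit_lambda(np.array([1.0, 2.0, 3.0, 4.0, 0.5]), star_tree)
        assert not fit.identifiable
        assert fit.lam == 0.0
        assert fit.pvalue == 1.0

    def test_loglik_ordering_invariant(self):
        assert_fit_beats_grid(seed=30)

    def test_zero_variance_rejected(self):
        tree = simulate_tree(10, seed=26)
        with pytest.raises(ValueError):
            fit_lambda(np.ones(10), tree)

    def test_se_variant_runs_and_nests(self):
        tree = simulate_tree(30, seed=27)
        _, x = simulate_bm_traits(tree, sigma2=1.0, lam=0.8, seed=28)
        fit = fit_lambda(x, tree, use_se=True, se=np.full(30, 0.1))
        assert fit.used_se
        assert fit.loglik >= fit.loglik_lambda0 - 1e-8
        assert 0.0 <= fit.lam <= fit.lambda_max


def assert_fit_beats_grid(seed: int, n_tips: int = 25, n_grid: int = 50) -> None:
    """The optimised λ likelihood must dominate a dense λ grid."""
    from camtraits.phylo import _gls_profile

    tree = simulate_tree(n_tips, seed=seed)
    _, x = simulate_bm_traits(tree, lam=0.5, seed=seed + 1)
    _, C = bm_covariance(tree)
    fit = fit_lambda(x, tree)
    grid_ll = [
        _gls_profile(x, lambda_transform(C, lam))[2]
        for lam in np.linspace(0.0, fit.lambda_max, n_grid)
    ]
    assert fit.loglik >= max(grid_ll) - 1e-6


class TestPgls:
    def test_star_tree_equals_ols(self, star_tree):
        rng = np.random.default_rng(31)
        x = rng.normal(size=5)
        y = 2 * x + rng.normal(size=5)
        fit = pgls(y, x, star_tree, structure="bm")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose(fit.coef, ols.params, atol=1e-10)
        assert np.allclose(fit.se, ols.bse, atol=1e-10)
        assert np.allclose(fit.p, ols.pvalues, atol=1e-10)

    def test_known_diagonal_v_equals_wls(self):
        # non-ultrametric star: tip variances 4,1,1,1,1 → weights 1/V_ii
        tree = tree_from_newick("(A:4,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(32)
        x = rng.normal(size=5)
        y = 1.5 * x + rng.normal(size=5)
        fit = pgls(y, x, tree, structure="bm")
        wls = sm.WLS(y, sm.add_constant(x), weights=1.0 / np.array([4, 1, 1, 1, 1])).fit()
        assert np.allclose(fit.coef, wls.params, atol=1e-10)
        assert np.allclose(fit.se, wls.bse, atol=1e-10)

    def test_slope_recovery_under_bm_residuals(self):
        tree = simulate_tree(40, seed=33)
        _, x = simulate_bm_traits(tree, sigma2=1.0, seed=34)
        _, noise = simulate_bm_traits(tree, sigma2=0.25, seed=35)
        y = 2.0 * x + noise
        fit = pgls(y, x, tree, structure="bm")
        assert abs(fit.coef[1] - 2.0) < 3 * fit.se[1]

    def test_lambda_structure_reduces_to_sensible_range(self):
        tree = simulate_tree(40, seed=36)
        _, x = simulate_bm_traits(tree, sigma2=1.0, seed=37)
        rng = np.random.default_rng(38)
        y = 1.0 * x + rng.normal(0, 0.5, 40)
        fit = pgls(y, x, tree, structure="lambda")
        assert 0.0 <= fit.lambda_used <= 1.0

    def test_rank_deficiency_rejected(self, star_tree):
        y = np.arange(5.0)
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError):
            pgls(y, X, star_tree, add_intercept=False)


class TestAncestralStates:
    def test_two_tip_midpoint_root(self):
        tree = tree_from_newick("(A:1,B:1);")
        anc = ancestral_states(np.array([0.0, 10.0]), tree)
        assert anc.root_state == pytest.approx(5.0)

    def test_constant_trait_constant_states(self, five_tip_tree):
        anc = ancestral_states(np.full(5, 3.0), five_tip_tree)
        assert np.allclose(anc.states, 3.0)

    def test_root_equals_gls_mean(self, five_tip_tree):
        rng = np.random.default_rng(40)
        x = rng.normal(size=5)
        fit = fit_lambda_root(five_tip_tree, x)
        anc = ancestral_states(x, five_tip_tree)
        assert anc.root_state == pytest.approx(fit, rel=1e-9)

    def test_against_joint_ml_optimiser(self, five_tip_tree):
        """Oracle: maximise the joint BM likelihood over all node values."""
        rng = np.random.default_rng(41)
        x = rng.normal(size=5)
        anc = ancestral_states(x, five_tip_tree)

        tree = five_tip_tree
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        node_index = {id(nd): k for k, nd in enumerate(internals)}
        leaves = list(tree.leaf_node_iter())
        leaf_index = {id(lf): k for k, lf in enumerate(leaves)}

        def neg_joint(theta):
            total = 0.0
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                val = (
                    x[leaf_index[id(nd)]] if nd.is_leaf() else theta[node_index[id(nd)]]
                )
                parent = theta[node_index[id(nd.parent_node)]]
                total += (val - parent) ** 2 / nd.edge.length
            return total

        res = minimize(neg_joint, np.zeros(len(internals)), method="BFGS")
        assert np.allclose(res.x, anc.states, atol=1e-5)

    def test_variances_positive_off_root(self, five_tip_tree):
        rng = np.random.default_rng(42)
        anc = ancestral_states(rng.normal(size=5), five_tip_tree)
        assert np.all(anc.variances >= 0.0)


def fit_lambda_root(tree, x):
    """GLS root estimate under plain BM, written out independently."""
    _, C = bm_covariance(tree)
    Ci = np.linalg.inv(C)
    ones = np.ones(len(x))
    return float(ones @ Ci @ x / (ones @ Ci @ ones))


class TestPruneAndLump:
    def _table(self, taxa, values):
        return pd.DataFrame({"taxon": taxa, "value": values})

    def test_identity_pruning(self, five_tip_tree):
        table = self._table(list("ABCDE"), [1.0, 2.0, 3.0, 4.0, 5.0])
        tree, out = prune_and_lump(five_tip_tree, table)
        assert leaf_labels(tree) == list(out["taxon"])
        assert len(out) == 5

    def test_lumped_taxa_pooled(self, five_tip_tree):
        table = self._table(["A", "A_sub", "B", "C", "D", "E"],
                            [1.0, 3.0, 2.0, 3.0, 4.0, 5.0])
        tree, out = prune_and_lump(five_tip_tree, table, lump_map={"A_sub": "A"})
        row = out[out.taxon == "A"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["n"] == 2

    def test_tips_without_data_pruned(self, five_tip_tree):
        table = self._table(["A", "B", "C"], [1.0, 2.0, 3.0])
        tree, out = prune_and_lump(five_tip_tree, table)
        assert sorted(leaf_labels(tree)) == ["A", "B", "C"]
        assert len(out) == 3

    def test_orphan_raises_with_names(self, five_tip_tree):
        table = self._table(["A", "Zz"], [1.0, 2.0])
        with pytest.raises(OrphanTaxonError, match="Zz"):
            prune_and_lump(five_tip_tree, table)
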