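"""PGLS engine: covariance construction, lambda transform, GLS fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from elevtrait.pgls import (LambdaGLS, adjusted_r2, bm_covariance,
                            build_design, lambda_transform, pgls_fit,
                            _fixed_lambda_fit)
from elevtrait.simulate import simulate_lambda_traits, simulate_yule_tree
from conftest import tip_labels


def brute_force_covariance(tree, species):
    """Independent oracle: pairwise MRCA depth by ancestor-set intersection."""
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    depth = {}
    for node in tree.preorder_node_iter():
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + (
            node.edge.length or 0.0)

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i == j:
                C[i, j] = depth[leaves[a]]
            else:
                anc_a = ancestors(leaves[a])
                anc_b = set(ancestors(leaves[b]))
                mrca = next(x for x in anc_a if x in anc_b)
                C[i, j] = depth[mrca]
    return C


class TestBMCovariance:
    def test_star_tree_is_diagonal(self, star_tree_40):
        sp = tip_labels(star_tree_40)
        C = bm_covariance(star_tree_40, sp)
        assert np.allclose(C, np.eye(40))

    def test_sister_pair_path_arithmetic(self, sister_tree):
        C = bm_covariance(sister_tree, ["A", "B", "C"])
        assert C[0, 1] == pytest.approx(0.6)
        assert np.allclose(np.diag(C), 1.0)
        assert C[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_mrca_oracle(self, seed):
        tree = simulate_yule_tree(12, 1.0, seed=seed)
        sp = tip_labels(tree)
        C = bm_covariance(tree, sp)
        assert np.allclose(C, brute_force_covariance(tree, sp), atol=1e-12)

    def test_missing_species_listed(self, sister_tree):
        with pytest.raises(KeyError, match="ghost"):
            bm_covariance(sister_tree, ["A", "B", "ghost"])


class TestLambdaTransform:
    def test_endpoints_and_midpoint(self, sister_tree):
        C = bm_covariance(sister_tree, ["A", "B", "C"])
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))
        assert lambda_transform(C, 0.5)[0, 1] == pytest.approx(0.3)

    def test_rejects_out_of_range(self, sister_tree):
        C = bm_covariance(sister_tree, ["A", "B", "C"])
        with pytest.raises(ValueError):
            lambda_transform(C, -0.1)


class TestPGLSFit:
    def test_lambda_zero_matches_ols(self, yule_tree_60):
        rng = np.random.default_rng(0)
        sp = tip_labels(yule_tree_60)
        x = rng.normal(size=60)
        y = 1.0 + 0.5 * x + rng.normal(size=60)
        fit = pgls_fit(pd.Series(y, index=sp),
                       pd.DataFrame({"x": x}, index=sp),
                       tree=yule_tree_60, lambda_mode=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-8)
        assert np.allclose(fit.bse, ols.bse, atol=1e-8)
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-8)

    def test_response_unit_change_scales_slope_only(self, yule_tree_60):
        rng = np.random.default_rng(1)
        sp = tip_labels(yule_tree_60)
        x = rng.normal(size=60)
        y = simulate_lambda_traits(yule_tree_60, 1.0, 1.0, 1, seed=3)[
            "trait_1"].to_numpy() + 2 * x
        X = pd.DataFrame({"x": x}, index=sp)
        f_m = pgls_fit(pd.Series(y * 1000.0, index=sp), X, tree=yule_tree_60)
        f_km = pgls_fit(pd.Series(y, index=sp), X, tree=yule_tree_60)
        assert f_m.lambda_hat == pytest.approx(f_km.lambda_hat, abs=1e-4)
        assert f_m.params["x"] == pytest.approx(1000.0 * f_km.params["x"],
                                                rel=1e-6)

    def test_profile_optimum_beats_fine_grid(self, yule_tree_60):
        sp = tip_labels(yule_tree_60)
        y = simulate_lambda_traits(yule_tree_60, 0.6, 1.0, 1, seed=8)["trait_1"]
        fit = pgls_fit(y, pd.DataFrame(index=pd.Index(sp)), tree=yule_tree_60)
        solver = LambdaGLS(bm_covariance(yule_tree_60, sp))
        X = np.ones((60, 1))
        grid_ll = [
            _fixed_lambda_fit(solver, g, X, y.to_numpy())[3]
            for g in np.linspace(0.0, 1.0, 101)
        ]
        assert fit.logL >= max(grid_ll) - 1e-6

    def test_aic_invariant_to_predictor_scaling(self, yule_tree_60):
        rng = np.random.default_rng(5)
        sp = tip_labels(yule_tree_60)
        x = rng.normal(size=60)
        y = simulate_lambda_traits(yule_tree_60, 0.8, 1.0, 1, seed=9)[
            "trait_1"] + 0.7 * x
        f1 = pgls_fit(y, pd.DataFrame({"x": x}, index=sp), tree=yule_tree_60)
        f2 = pgls_fit(y, pd.DataFrame({"x": (x - 3.0) / 17.0}, index=sp),
                      tree=yule_tree_60)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-6)

    def test_slope_recovery_under_brownian_noise(self):
        hits, lams = 0, []
        n_reps = 25
        for rep in range(n_reps):
            tree = simulate_yule_tree(150, 1.0, seed=500 + rep)
            sp = tip_labels(tree)
            rng = np.random.default_rng(900 + rep)
            x = rng.normal(size=150)
            noise = simulate_lambda_traits(tree, 1.0, 1.0, 1,
                                           seed=700 + rep)["trait_1"]
            y = 2.0 + 3.0 * x + noise
            fit = pgls_fit(y, pd.DataFrame({"x": x}, index=sp), tree=tree)
            hits += abs(fit.params["x"] - 3.0) <= 3.0 * fit.bse["x"]
            lams.append(fit.lambda_hat)
        assert hits >= int(0.9 * n_reps)
        assert np.median(lams) >= 0.8

    def test_singular_design_names_collinear_column(self, yule_tree_60):
        sp = tip_labels(yule_tree_60)
        x = np.arange(60.0)
        X = pd.DataFrame({"x": x, "x2": 2.0 * x}, index=sp)
        with pytest.raises(ValueError, match="x2"):
            pgls_fit(pd.Series(np.ones(60), index=sp), X, tree=yule_tree_60)

    def test_nonfinite_rejected(self, yule_tree_60):
        sp = tip_labels(yule_tree_60)
        y = np.ones(60)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pgls_fit(pd.Series(y, index=sp), pd.DataFrame(index=pd.Index(sp)),
                     tree=yule_tree_60)


class TestAdjustedR2:
    def test_arithmetic(self, yule_tree_60):
        # 1 - 0.5 * 100 / 98 from r2=0.5, n=101, p=2
        class F:
            n, n_predictors, r2 = 101, 2, 0.5
        assert adjusted_r2(F()) == pytest.approx(1 - 0.5 * 100 / 98)

    def test_bounds(self):
        class F:
            n, n_predictors, r2 = 50, 3, 0.0
        assert adjusted_r2(F()) <= 0.0
        F.r2 = 1.0
        assert adjusted_r2(F()) == pytest.approx(1.0)

    def test_undefined_when_saturated(self):
        class F:
            n, n_predictors, r2 = 4, 3, 0.9
        assert np.isnan(adjusted_r2(F()))


class TestBuildDesign:
    def test_categorical_reference_coding(self):
        tab = pd.DataFrame({"gf": ["A", "C", "W", "A"],
                            "h": [1.0, 2.0, 3.0, 4.0]},
                           index=list("wxyz"))
        design, groups = build_design(tab, ["h", "gf"])
        assert groups["gf"] == ["gf[C]", "gf[W]"]  # reference 'A' dropped
        assert design["gf[C]"].tolist() == [0.0, 1.0, 0.0, 0.0]
        assert groups["h"] == ["h"]
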