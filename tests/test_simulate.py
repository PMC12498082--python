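"""Synthetic-data generator: tree shape, trait covariance, optima, occurrences."""

import numpy as np
import pandas as pd
import pytest

from elevtrait.pgls import bm_covariance
from elevtrait.simulate import (GROWTH_FORMS, SimulationConfig,
                                compose_optima, hofiv_presence_prob,
                                simulate_dataset, simulate_lambda_traits,
                                simulate_occurrences, simulate_trait_table,
                                simulate_yule_tree)
from conftest import tip_labels


class TestYuleTree:
    def test_two_tips_equal_depths(self):
        tree = simulate_yule_tree(2, 1.0, seed=1)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert len(depths) == 2
        assert depths[0] == pytest.approx(depths[1])

    def test_deterministic_under_seed(self):
        a = simulate_yule_tree(50, 1.0, seed=7).as_string(schema="newick")
        b = simulate_yule_tree(50, 1.0, seed=7).as_string(schema="newick")
        assert a == b

    def test_binary_rooted_node_count(self):
        tree = simulate_yule_tree(310, 1.0, seed=3)
        assert len(tree.leaf_nodes()) == 310
        assert len(tree.nodes()) == 2 * 310 - 1  # binary rooted identity
        labels = tip_labels(tree)
        assert len(set(labels)) == 310

    def test_unit_height_ultrametric(self):
        tree = simulate_yule_tree(30, 2.0, seed=9)
        depths = np.array([l.distance_from_root() for l in tree.leaf_node_iter()])
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_rejects_tiny_or_invalid(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, -1.0, seed=0)


class TestLambdaTraits:
    def test_lambda_zero_gives_independent_tips(self, sister_tree):
        # many replicate traits on one tree: empirical covariance ~ sigma2 I
        X = simulate_lambda_traits(sister_tree, 0.0, sigma2=2.0,
                                   n_traits=4000, seed=5)
        emp = np.cov(X.to_numpy())
        assert np.allclose(np.diag(emp), 2.0, atol=0.25)
        off = emp[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.25

    def test_brownian_sister_correlation_equals_shared_fraction(self, sister_tree):
        X = simulate_lambda_traits(sister_tree, 1.0, sigma2=1.0,
                                   n_traits=4000, seed=6)
        corr = np.corrcoef(X.loc["A"], X.loc["B"])[0, 1]
        assert corr == pytest.approx(0.6, abs=0.06)

    def test_deterministic_under_seed(self, yule_tree_60):
        a = simulate_lambda_traits(yule_tree_60, 0.5, 1.0, 3, seed=2)
        b = simulate_lambda_traits(yule_tree_60, 0.5, 1.0, 3, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_lambda_outside_unit_interval(self, yule_tree_60):
        with pytest.raises(ValueError):
            simulate_lambda_traits(yule_tree_60, 1.5, 1.0, 1, seed=0)


class TestTraitTable:
    def test_invariants(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4)
        for col in ("Mechanical tissue", "Storage tissue", "LCC", "Starch",
                    "Fructan", "Free sugar"):
            assert tab[col].between(0, 100).all()
        for col in ("Height", "Longevity", "Ring width"):
            assert (tab[col] >= 0).all()
        assert set(tab["growth_form"]) <= set(GROWTH_FORMS)
        assert tab.index.is_unique
        # all seven growth forms populated at n=60 with septile bins
        assert tab["growth_form"].nunique() == 7


class TestComposeOptima:
    def test_zero_betas_zero_noise_gives_intercept(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4)
        opt, clipped = compose_optima(tab, {}, 4500.0, 0.0, seed=0)
        assert (opt == 4500.0).all()
        assert clipped == []

    def test_linear_arithmetic(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4).copy()
        tab.loc[tab.index[0], "Height"] = 20.0
        opt, _ = compose_optima(tab, {"Height": -10.0}, 4500.0, 0.0, seed=0)
        assert opt.iloc[0] == pytest.approx(4300.0)

    def test_noise_sd_recovered(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4)
        reps = []
        for s in range(5):
            opt, _ = compose_optima(tab, {}, 4500.0, 300.0, seed=s)
            reps.append(np.std(opt - 4500.0, ddof=1))
        assert 200.0 < np.mean(reps) < 400.0

    def test_unknown_trait_raises(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4)
        with pytest.raises(KeyError):
            compose_optima(tab, {"NotATrait": 1.0}, 4500.0, 0.0, seed=0)

    def test_clipping_is_logged(self, yule_tree_60):
        tab = simulate_trait_table(yule_tree_60, 0.5, seed=4)
        opt, clipped = compose_optima(tab, {}, 7000.0, 0.0, seed=0,
                                      elev_range=(2650.0, 6150.0))
        assert (opt == 6150.0).all()
        assert len(clipped) == len(tab)


class TestOccurrences:
    def test_zero_max_prob_zero_presences(self):
        opt = pd.Series([4000.0], index=["spA"])
        occ = simulate_occurrences(opt, 400.0, 0.0, 500, (2650, 6150), seed=1)
        assert occ["present"].sum() == 0
        assert len(occ) == 500

    def test_peak_presence_near_optimum(self):
        opt = pd.Series([4400.0], index=["spA"])
        occ = simulate_occurrences(opt, 400.0, 0.8, 10_000, (2650, 6150), seed=2)
        bins = np.arange(2650, 6250, 100.0)
        grp = occ.groupby(pd.cut(occ["elevation_m"], bins, labels=bins[:-1]),
                          observed=True)["present"].mean()
        peak_bin = float(grp.idxmax())
        assert abs(peak_bin + 50.0 - 4400.0) <= 150.0  # within +/- 1 bin

    def test_total_count_matches_binomial_expectation(self):
        opt = pd.Series([4400.0], index=["spA"])
        n_loc = 20_000
        occ = simulate_occurrences(opt, 400.0, 0.8, n_loc, (2650, 6150), seed=3)
        grid = np.linspace(2650, 6150, 20_001)
        mean_p = hofiv_presence_prob(grid, 4400.0, 400.0, 0.8).mean()
        expect = n_loc * mean_p
        sd = np.sqrt(n_loc * mean_p * (1 - mean_p))
        assert abs(occ["present"].sum() - expect) <= 3 * sd

    def test_rejects_empty_range(self):
        with pytest.raises(ValueError):
            simulate_occurrences(pd.Series([4000.0], index=["a"]),
                                 400.0, 0.5, 10, (5000, 5000), seed=0)


class TestDataset:
    def test_byte_identical_under_seed(self):
        cfg = SimulationConfig(n_species=12, n_localities=50, seed=9)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert (a["traits"].to_csv() == b["traits"].to_csv())
        assert (a["occurrences"].to_csv() == b["occurrences"].to_csv())
        assert (a["tree"].as_string(schema="newick")
                == b["tree"].as_string(schema="newick"))

    def test_habitat_pools_match_configured_split(self):
        cfg = SimulationConfig(n_species=31, habitat_split=(169, 141),
                               n_localities=10, seed=1)
        d = simulate_dataset(cfg)
        counts = d["traits"]["habitat"].value_counts()
        assert counts["steppe"] == 17  # 31 * 169/310 rounded
        assert counts["alpine"] == 14
        # steppe pool sits lower on the gradient
        t = d["traits"]
        assert (t.loc[t.habitat == "steppe", "true_optimum"].median()
                < t.loc[t.habitat == "alpine", "true_optimum"].median())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(lambda_true=2.0)
        with pytest.raises(ValueError):
            SimulationConfig(elev_range=(5000.0, 3000.0))
        with pytest.raises(ValueError):
            SimulationConfig(max_prob=1.5)
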