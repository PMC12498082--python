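"""Transforms, Holm step-down control, scans, and habitat contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elevtrait.screen import (PUBLISHED_TABLE, default_transforms, habitat_contrast,
                              holm_bonferroni, parse_p,
                              replay_published_decisions,
                              single_predictor_scan, transform_predictor)
from elevtrait.simulate import (SimulationConfig, simulate_dataset,
                                simulate_lambda_traits, simulate_yule_tree)
from conftest import tip_labels


class TestTransform:
    def test_log_substitutes_half_second_smallest(self):
        out, prov = transform_predictor([0.0, 1.0, 3.0], "log")
        assert out == pytest.approx([np.log(0.5), 0.0, np.log(3.0)])
        assert prov["zeros_substituted"] == 1
        assert prov["substitute_value"] == pytest.approx(0.5)

    def test_none_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        out, prov = transform_predictor(x, "none")
        assert np.array_equal(out, x)
        assert prov["rule"] == "none"

    def test_log_without_zeros_logs_nothing_extra(self):
        out, prov = transform_predictor([1.0, 2.0], "log")
        assert out == pytest.approx(np.log([1.0, 2.0]))
        assert prov["zeros_substituted"] == 0
        assert "substitute_value" not in prov

    def test_negative_under_sqrt_names_trait(self):
        with pytest.raises(ValueError, match="d13C"):
            transform_predictor([-1.0, 2.0], "sqrt", name="d13C")

    def test_heuristic_rules(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({
            "skewed_pos": np.exp(rng.normal(0, 1.5, 300)),
            "skewed_zeros": np.r_[np.zeros(80), np.exp(rng.normal(0, 1.5, 220))],
            "symmetric": rng.normal(0, 1, 300),
            "negative": rng.normal(-27, 2, 300),
        })
        rules = default_transforms(tab, tab.columns)
        assert rules == {"skewed_pos": "log", "skewed_zeros": "sqrt",
                         "symmetric": "none", "negative": "none"}


class TestHolm:
    def test_all_ones_no_rejections(self):
        assert not holm_bonferroni([1.0] * 5).any()

    def test_single_p_plain_alpha(self):
        assert holm_bonferroni([0.04]).tolist() == [True]

    def test_step_down_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, 12) ** 3
            got = holm_bonferroni(p, 0.05)
            # independent step-down loop
            order = np.argsort(p, kind="stable")
            expect = np.zeros(12, dtype=bool)
            for rank, i in enumerate(order):
                if p[i] <= 0.05 / (12 - rank):
                    expect[i] = True
                else:
                    break
            assert np.array_equal(got, expect)

    def test_order_invariance_and_alpha_monotonicity(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.2, 10)
        perm = rng.permutation(10)
        assert np.array_equal(holm_bonferroni(p)[perm], holm_bonferroni(p[perm]))
        assert holm_bonferroni(p, 0.01).sum() <= holm_bonferroni(p, 0.05).sum()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_decisions_monotone_in_raw_p(self, ps):
        dec = holm_bonferroni(ps)
        p = np.asarray(ps)
        if dec.any():
            assert p[dec].max() <= p[~dec].min() if (~dec).any() else True

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestPublishedReplay:
    def test_all_three_columns_reproduced(self):
        rep = replay_published_decisions()
        for col, n_expected in (("contrast", 10), ("steppe", 2), ("alpine", 10)):
            tested = rep[f"{col}_p"].notna()
            assert (rep.loc[tested, f"{col}_rejected"]
                    == rep.loc[tested, f"{col}_printed_star"]).all()
            assert rep[f"{col}_rejected"].sum() == n_expected

    def test_key_individual_decisions(self):
        rep = replay_published_decisions().set_index("trait")
        assert rep.loc["Storage tissue", "alpine_rejected"]      # p = 0.0001
        assert not rep.loc["Starch", "alpine_rejected"]          # p = 0.22
        assert not rep.loc["Starch", "contrast_rejected"]        # p = 0.01
        assert not rep.loc["d13C", "contrast_rejected"]          # p = 0.037
        assert not rep.loc["LNC", "contrast_rejected"]           # p = 0.052
        assert not rep.loc["d13C", "steppe_rejected"]            # p = 0.004

    def test_bound_entries_parsed_at_bound(self):
        assert parse_p("<0.0001") == pytest.approx(1e-4)
        assert parse_p("0.052") == pytest.approx(0.052)


@pytest.fixture(scope="module")
def scan_dataset():
    cfg = SimulationConfig(n_species=80, n_localities=10, seed=21,
                           beta_true={"Height": -40.0},
                           optimum_intercept=5800.0, optimum_noise_sd=150.0)
    d = simulate_dataset(cfg)
    traits = d["traits"].copy()
    return traits, d["traits"]["true_optimum"], d["tree"]


class TestScan:
    def test_planted_negative_height_effect_flagged(self, scan_dataset):
        traits, optima, tree = scan_dataset
        for hab in ("steppe", "alpine"):
            scan = single_predictor_scan(traits, optima, tree, hab)
            row = scan.set_index("trait").loc["Height"]
            assert row["significant"]
            assert row["direction"] == "down"
            assert row["slope"] < 0

    def test_one_row_per_trait_and_direction_consistency(self, scan_dataset):
        traits, optima, tree = scan_dataset
        scan = single_predictor_scan(traits, optima, tree, "alpine")
        assert scan["trait"].is_unique
        for _, r in scan.iterrows():
            if r["direction"]:
                assert r["p_raw"] < 0.05
                assert (r["slope"] > 0) == (r["direction"] == "up")

    def test_unknown_habitat_rejected(self, scan_dataset):
        traits, optima, tree = scan_dataset
        with pytest.raises(ValueError):
            single_predictor_scan(traits, optima, tree, "montane")


class TestContrast:
    def test_single_habitat_rejected(self, scan_dataset):
        traits, _, tree = scan_dataset
        only = traits[traits["habitat"] == "alpine"]
        with pytest.raises(ValueError, match="both habitats"):
            habitat_contrast("Height", only, tree)

    def test_planted_shift_detected(self):
        tree = simulate_yule_tree(150, seed=31)
        sp = tip_labels(tree)
        rng = np.random.default_rng(31)
        hab = np.array(["steppe"] * 75 + ["alpine"] * 75)
        x = rng.normal(0, 1, 150) + np.where(hab == "alpine", 2.0, 0.0)
        tab = pd.DataFrame({"Height": x, "habitat": hab}, index=sp)
        res = habitat_contrast("Height", tab, tree)
        assert res["pvalue"] < 1e-6
        welch = habitat_contrast("Height", tab, tree, method="welch")
        assert welch["method"] == "welch"
        assert welch["pvalue"] < 1e-6

    def test_null_calibration_approximately_uniform(self):
        # identical group means, labels random w.r.t. phylogeny: p ~ uniform
        from scipy.stats import kstest

        tree = simulate_yule_tree(60, seed=40)
        sp = tip_labels(tree)
        pvals = []
        n_reps = 300
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            hab = np.array(["steppe"] * 30 + ["alpine"] * 30)
            rng.shuffle(hab)
            x = simulate_lambda_traits(tree, 0.5, 1.0, 1,
                                       seed=5000 + rep)["trait_1"]
            tab = pd.DataFrame({"t": x.to_numpy(), "habitat": hab}, index=sp)
            pvals.append(habitat_contrast("t", tab, tree)["pvalue"])
        assert kstest(pvals, "uniform").pvalue > 0.01
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate < 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_reps) + 0.02
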