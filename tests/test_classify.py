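"""Classifier machinery: grids, thresholds, AUC/DeLong, CV selection and
the hold-one-institution-out protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, ttest_rel

from pzrad.classify import (
    augmentation_tests,
    delong_compare,
    hold_one_site_out,
    inner_cv_train,
    make_c_grid,
    paired_site_ttest,
    results_table,
    roc_auc_ci,
    site_performance,
    youden_threshold,
)

from conftest import make_synthetic_feature_table


class TestCGrid:
    def test_seven_log_spaced_values(self):
        grid = make_c_grid()
        assert len(grid) == 7
        assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(10.0)
        np.testing.assert_allclose(np.diff(np.log10(grid)), np.log10(grid[1] / grid[0]))


class TestYouden:
    def test_perfect_separation(self):
        thr, j, anti = youden_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert 0.2 < thr < 0.8
        assert j == pytest.approx(1.0)
        assert not anti

    def test_tie_breaks_to_higher_threshold(self):
        # both candidate cuts reach J = 0.5; the higher one must win
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 1, 0, 1])
        thr, j, _ = youden_threshold(scores, labels)
        assert j == pytest.approx(0.5)
        assert thr == pytest.approx(2.5)

    def test_anti_separated_flagged(self):
        thr, j, anti = youden_threshold(np.array([0.9, 0.8, 0.1, 0.2]), np.array([0, 0, 1, 1]))
        assert anti and j <= 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold(np.array([1.0, 2.0]), np.array([1, 1]))


class TestAuc:
    def test_equals_u_over_n1n0(self, rng):
        for _ in range(20):
            n1, n0 = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            scores = rng.standard_normal(n1 + n0)
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            auc, _ = roc_auc_ci(scores, labels)
            u = mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_perfect_and_reversed(self):
        labels = np.array([0, 0, 1, 1])
        auc, ci = roc_auc_ci(np.array([1.0, 2.0, 3.0, 4.0]), labels)
        assert auc == 1.0 and ci[1] <= 1.0
        auc, _ = roc_auc_ci(np.array([4.0, 3.0, 2.0, 1.0]), labels)
        assert auc == 0.0

    def test_ci_contains_auc_and_is_ordered(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        auc, (lo, hi) = roc_auc_ci(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci(np.array([1.0, 2.0]), np.array([1, 1]))


class TestDelong:
    def test_symmetry(self, rng):
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        a = rng.standard_normal(30) + labels
        b = rng.standard_normal(30) + 0.5 * labels
        p_ab, _ = delong_compare(a, b, labels)
        p_ba, _ = delong_compare(b, a, labels)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
        assert 0.0 <= p_ab <= 1.0

    def test_identical_scores_degenerate(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        s = np.arange(6, dtype=float)
        p, degen = delong_compare(s, s, labels)
        assert degen and p == 1.0

    def test_detects_clear_improvement(self):
        """Strongly informative vs pure-noise scores on 200 tumors should be
        declared different in most repetitions."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.r_[np.ones(100, int), np.zeros(100, int)]
            good = 2.0 * labels + rng.standard_normal(200)
            noise = rng.standard_normal(200)
            p, _ = delong_compare(good, noise, labels)
            hits += p < 0.05
        assert hits >= 18

    def test_small_sample_permutation_calibrated(self):
        """With tiny test sets (4 vs 4) the sign-swap permutation path must
        hold its level under the null — the asymptotic z-test does not."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(30_000 + seed)
            labels = np.r_[np.ones(4, int), np.zeros(4, int)]
            p, _ = delong_compare(rng.standard_normal(8), rng.standard_normal(8), labels)
            hits += p < 0.05
        assert hits <= 20  # level 0.05, generous binomial margin

    def test_small_sample_deterministic(self):
        rng = np.random.default_rng(31)
        labels = np.r_[np.ones(6, int), np.zeros(7, int)]
        a, b = rng.standard_normal(13), rng.standard_normal(13)
        assert delong_compare(a, b, labels) == delong_compare(a, b, labels)

    def test_null_uniform_type_one(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            labels = np.r_[np.ones(40, int), np.zeros(40, int)]
            p, _ = delong_compare(rng.standard_normal(80), rng.standard_normal(80), labels)
            hits += p < 0.05
        assert hits <= 12  # ~binomial(100, 0.05) upper tail


class TestSitePerformance:
    def test_confusion_arithmetic(self):
        # 4 positives: 3 above threshold (TP), 1 below (FN)
        # 5 negatives: 4 below (TN), 1 above (FP)
        scores = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0, -1.0, 1.0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0])
        acc, sens, spec = site_performance(scores, labels, threshold=0.0)
        assert sens == pytest.approx(3 / 4)
        assert spec == pytest.approx(4 / 5)
        assert acc == pytest.approx((3 / 4 + 4 / 5) / 2)

    def test_missing_class_gives_nan_member(self):
        acc, sens, spec = site_performance(np.array([1.0, -1.0]), np.array([1, 1]), 0.0)
        assert np.isnan(spec) and sens == pytest.approx(0.5) and acc == pytest.approx(0.5)


class TestPairedTtest:
    def test_matches_scipy(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        p, degen = paired_site_ttest(a, b)
        assert not degen
        assert p == pytest.approx(float(ttest_rel(a, b).pvalue), abs=1e-12)

    def test_constant_difference_degenerate(self):
        a = np.array([0.7, 0.8, 0.9])
        p, degen = paired_site_ttest(a, a + 0.1)
        assert degen and p == 1.0

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            paired_site_ttest([0.5, 0.6], [0.5, 0.7])


class TestInnerCv:
    FEATS = ["inf0", "inf1"] + [f"noise{j}" for j in range(8)]

    def test_recovers_informative_features(self):
        """With 2 strongly informative of 10 features, the selected subset
        contains both informative features in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            table = make_synthetic_feature_table(effect=3.0, seed=seed, patients_per_site=10)
            model = inner_cv_train(table, self.FEATS, seed=seed)
            hits += {"inf0", "inf1"} <= set(model.selected_features)
        assert hits >= 18

    def test_permuted_labels_give_chance_level_cv_error(self):
        """Destroying the labels must push the inner-CV balanced error toward
        0.5 (above 0.3 in at least 8 of 10 seeds)."""
        high = 0
        for seed in range(10):
            table = make_synthetic_feature_table(effect=3.0, seed=seed, patients_per_site=10)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(table))
            table = table.assign(
                aggressiveness=table["aggressiveness"].to_numpy()[perm],
                grade_group=table["grade_group"].to_numpy()[perm],
            )
            if table["aggressiveness"].nunique() < 2:
                continue
            model = inner_cv_train(table, self.FEATS, seed=seed)
            high += model.cv_error > 0.3
        assert high >= 8

    def test_tumors_of_a_patient_share_folds(self):
        """With two identical tumors per patient, patient-level folding keeps
        duplicates out of the validation folds, so the cv error on permuted
        labels stays at chance instead of collapsing toward 0 (which is what
        record-level folding would produce with duplicated rows)."""
        table = make_synthetic_feature_table(
            effect=0.0, n_informative=0, n_noise=6, seed=3,
            patients_per_site=10, tumors_per_patient=2,
        )
        # duplicate each patient's first tumor features into the second
        first = table.groupby("patient_id").head(1).set_index("patient_id")
        for col in [f"noise{j}" for j in range(6)]:
            table[col] = table["patient_id"].map(first[col])
        model = inner_cv_train(table, [f"noise{j}" for j in range(6)], seed=3)
        assert model.cv_error > 0.3

    def test_few_patients_rejected(self):
        table = make_synthetic_feature_table(n_sites=2, patients_per_site=4, seed=0)
        with pytest.raises(ValueError, match="10 patients"):
            inner_cv_train(table, self.FEATS, seed=0)

    def test_single_class_rejected(self):
        table = make_synthetic_feature_table(seed=0)
        table["aggressiveness"] = "low"
        with pytest.raises(ValueError, match="degenerate"):
            inner_cv_train(table, self.FEATS, seed=0)

    def test_deterministic(self):
        table = make_synthetic_feature_table(effect=2.0, seed=9, patients_per_site=10)
        m1 = inner_cv_train(table, self.FEATS, seed=9)
        m2 = inner_cv_train(table, self.FEATS, seed=9)
        assert m1.selected_features == m2.selected_features
        assert m1.C == m2.C and m1.youden_threshold == m2.youden_threshold
        np.testing.assert_array_equal(m1.coef, m2.coef)


def _two_set_config():
    return {
        "informative": ("inf0", "inf1"),
        "all": ("inf0", "inf1") + tuple(f"noise{j}" for j in range(4)),
    }


class TestHoldOneSiteOut:
    def test_partition_and_shapes(self):
        table = make_synthetic_feature_table(effect=3.0, seed=7, patients_per_site=8, n_noise=4)
        results = hold_one_site_out(table, feature_sets=_two_set_config(), seed=7)
        sites = sorted(table["site_id"].unique())
        assert len(results) == len(sites) * 2
        for r in results:
            n_site = (table["site_id"] == r.held_out_site).sum()
            assert len(r.test_scores) == n_site == len(r.test_labels)
        held = sorted({r.held_out_site for r in results})
        assert held == sites

    def test_strong_effect_high_auc(self):
        table = make_synthetic_feature_table(effect=3.0, seed=7, patients_per_site=8, n_noise=4)
        results = hold_one_site_out(table, feature_sets=_two_set_config(), seed=7)
        perf = results_table(results)
        assert perf["auc"].mean() > 0.9

    def test_site_confounded_feature_screened_out(self):
        """A feature that is pure site offset must not be selected when the
        train-only screen is on."""
        table = make_synthetic_feature_table(
            effect=3.0, seed=5, patients_per_site=8, n_noise=4
        )
        site_idx = table["site_id"].str.slice(1).astype(int)
        rng = np.random.default_rng(5)
        table["noise0"] = 3.0 * site_idx + rng.standard_normal(len(table))
        results = hold_one_site_out(table, feature_sets=_two_set_config(), seed=5)
        for r in results:
            if r.feature_set == "all":
                assert "noise0" not in r.model.selected_features

    def test_single_site_rejected(self):
        table = make_synthetic_feature_table(n_sites=1, patients_per_site=12, seed=0)
        with pytest.raises(ValueError, match="at least 2 sites"):
            hold_one_site_out(table, feature_sets=_two_set_config(), seed=0)

    def test_results_table_columns(self):
        table = make_synthetic_feature_table(effect=3.0, seed=7, patients_per_site=8, n_noise=4)
        results = hold_one_site_out(table, feature_sets=_two_set_config(), seed=7)
        perf = results_table(results)
        assert {"held_out_site", "feature_set", "auc", "accuracy", "sensitivity",
                "specificity", "C", "n_selected"} <= set(perf.columns)


class TestAugmentation:
    def test_structure_and_ranges(self):
        table = make_synthetic_feature_table(effect=3.0, seed=11, patients_per_site=8, n_noise=4)
        sets = {"adc_t2w_hist": ("inf0",), "adc_t2w_hist_texture": ("inf0", "inf1")}
        results = hold_one_site_out(table, feature_sets=sets, seed=11)
        aug = augmentation_tests(results)
        assert set(aug["delong_p_by_site"]) == set(table["site_id"].unique())
        for p in aug["delong_p_by_site"].values():
            assert 0.0 <= p <= 1.0
        for q, p in zip(aug["delong_q_by_site"].values(), aug["delong_p_by_site"].values()):
            assert q >= p - 1e-15
        assert 0.0 <= aug["paired_t_auc_p"] <= 1.0
        assert 0.0 <= aug["paired_t_acc_p"] <= 1.0
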