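"""Feature assembly, SVM training/evaluation, robustness, distributions."""

import numpy as np
import pandas as pd
import pytest

from rotortether.substrate_classifier import (build_feature_table,
                                              group_parameter_stats,
                                              kde_distribution,
                                              metrics_from_confusion,
                                              noise_robustness, train_svm)
from rotortether.synthetic_cohort import make_virtual_cohort


@pytest.fixture(scope="module")
def cohort():
    return make_virtual_cohort(6, seed=7, dx=3.0)


@pytest.fixture(scope="module")
def table(cohort):
    return build_feature_table(cohort, include_surface=True)


class TestFeatureTable:
    def test_one_row_per_case_node(self, cohort, table):
        assert len(table) == sum(c.domain.n_nodes for c in cohort)
        assert table.groupby(["case_id", "node_id"]).size().max() == 1

    def test_surface_column_controlled_by_flag(self, cohort):
        t2 = build_feature_table(cohort, include_surface=False)
        assert "surface_cm2" not in t2.columns
        t3 = build_feature_table(cohort, include_surface=True)
        assert "surface_cm2" in t3.columns

    def test_empty_masks_label_everything_normal(self, cohort):
        empty = [np.zeros(c.domain.n_nodes, dtype=bool) for c in cohort]
        t = build_feature_table(cohort, masks=empty)
        assert (t["label"] == "normal").all()

    def test_missing_mask_rejected(self, cohort):
        masks = [c.true_mask for c in cohort]
        masks[2] = None
        with pytest.raises(ValueError, match="mask"):
            build_feature_table(cohort, masks=masks)


class TestMetrics:
    def test_consistency_with_confusion_counts(self, table):
        fitted = train_svm(table, include_surface=True, seed=3)
        tn, fp, fn, tp = fitted.report.confusion
        m = metrics_from_confusion(tn, fp, fn, tp)
        assert fitted.report.accuracy == pytest.approx(m["accuracy"], abs=1e-12)
        assert fitted.report.sensitivity == pytest.approx(m["sensitivity"], abs=1e-12)
        assert fitted.report.specificity == pytest.approx(m["specificity"], abs=1e-12)
        assert fitted.report.f1 == pytest.approx(m["f1"], abs=1e-12)


class TestTraining:
    def test_separable_planted_rule_is_learned_perfectly(self, table):
        """Label = (CV_max below threshold): a separable rule in feature
        space must give held-out accuracy 1.0."""
        t = table[(table["cv_max"] < 95.0) | (table["cv_max"] > 105.0)].copy()
        t["label"] = np.where(t["cv_max"] < 100.0, "tethering", "normal")
        fitted = train_svm(t, include_surface=False, seed=1)
        assert fitted.report.accuracy == 1.0

    def test_permutation_null_is_chance_level(self, table):
        accs = []
        for seed in range(10):
            t = table.copy()
            rng = np.random.default_rng(seed)
            t["label"] = rng.permutation(t["label"].to_numpy())
            fitted = train_svm(t, include_surface=False, seed=seed,
                               max_rows=4000)
            accs.append(fitted.report.balanced_accuracy)
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_single_class_training_rejected(self, table):
        t = table.copy()
        t["label"] = "normal"
        with pytest.raises(ValueError, match="tethering"):
            train_svm(t, seed=0)

    def test_grouped_split_respects_cases(self, table):
        fitted = train_svm(table, include_surface=True, split="grouped", seed=2)
        assert fitted.report.split == "grouped"
        assert 0.5 < fitted.report.balanced_accuracy <= 1.0

    def test_scaler_fitted_on_training_rows_only(self, table):
        """No standardization leakage: the scaler is reproducible from the
        training split alone and its statistics are not the full-table
        statistics."""
        fitted1 = train_svm(table, include_surface=True, seed=11)
        fitted2 = train_svm(table.copy(), include_surface=True, seed=11)
        assert np.allclose(fitted1.train_mean, fitted2.train_mean)
        X = table[["cv_max", "apd_max", "surface_cm2"]].to_numpy()
        assert not np.allclose(fitted1.train_mean, X.mean(axis=0), rtol=1e-6)


class TestBayesRateRecovery:
    def test_accuracy_tracks_monte_carlo_bayes_rate(self):
        """Overlapping class-conditional Gaussians with a known Bayes rate:
        the SVM's held-out balanced accuracy lands within 3 points."""
        rng = np.random.default_rng(42)
        n = 4000
        mu0, mu1 = np.array([160.0, 180.0]), np.array([100.0, 140.0])
        sd = np.array([35.0, 30.0])
        X0 = rng.normal(mu0, sd, size=(n, 2))
        X1 = rng.normal(mu1, sd, size=(n, 2))
        # Monte-Carlo Bayes rate from the true densities (balanced prior)
        def loglik(X, mu):
            return -0.5 * np.sum(((X - mu) / sd) ** 2, axis=1)
        bayes = 0.5 * (np.mean(loglik(X0, mu0) > loglik(X0, mu1)) +
                       np.mean(loglik(X1, mu1) > loglik(X1, mu0)))
        t = pd.DataFrame({
            "case_id": 1, "node_id": np.arange(2 * n),
            "cv_max": np.concatenate([X0[:, 0], X1[:, 0]]),
            "apd_max": np.concatenate([X0[:, 1], X1[:, 1]]),
            "label": ["normal"] * n + ["tethering"] * n,
        })
        fitted = train_svm(t, include_surface=False, seed=5,
                           subsample_negatives=None)
        assert fitted.report.balanced_accuracy == pytest.approx(bayes, abs=0.03)


class TestSurfaceFeature:
    def _surface_rule_table(self, seed):
        # large patches so the slow-CV population is a sizeable tissue
        # fraction; the rule labels it tethering only in large atria
        cases = make_virtual_cohort(8, seed=seed, dx=3.0,
                                    tethering_rule="cv_and_surface",
                                    patch_radius_range=(50.0, 70.0))
        return build_feature_table(cases, include_surface=True)

    def test_informative_surface_feature_improves_accuracy(self):
        """When the planted rule depends on atrial size, adding the surface
        feature buys >= 3 points of balanced accuracy (the qualitative
        analogue of the 2-feature vs 3-feature classifier gap)."""
        gains = []
        for seed in range(10):
            t = self._surface_rule_table(seed)
            if (t["label"] == "tethering").sum() < 10:
                continue
            f2 = train_svm(t, include_surface=False, seed=seed, max_rows=6000)
            f3 = train_svm(t, include_surface=True, seed=seed, max_rows=6000)
            gains.append(f3.report.balanced_accuracy -
                         f2.report.balanced_accuracy)
        assert np.mean(gains) >= 0.03

    def test_uninformative_surface_feature_harmless(self, table):
        """Adding surface when the rule ignores it costs < 1 point."""
        losses = []
        for seed in range(10):
            f2 = train_svm(table, include_surface=False, seed=seed,
                           max_rows=6000)
            f3 = train_svm(table, include_surface=True, seed=seed,
                           max_rows=6000)
            losses.append(f2.report.balanced_accuracy -
                          f3.report.balanced_accuracy)
        assert np.mean(losses) <= 0.01


class TestNoiseRobustness:
    def test_zero_noise_reproduces_clean_report(self, table):
        fitted = train_svm(table, include_surface=True, seed=4)
        rep = noise_robustness(fitted, 0.0, seed=9)
        assert rep.accuracy == fitted.report.accuracy
        assert rep.confusion == fitted.report.confusion

    def test_accuracy_degrades_monotonically_in_expectation(self, table):
        fitted = train_svm(table, include_surface=True, seed=4)
        means = []
        for frac in (0.0, 0.1, 0.5):
            accs = [noise_robustness(fitted, frac, seed=s).accuracy
                    for s in range(10)]
            means.append(np.mean(accs))
        assert means[0] >= means[1] - 1e-6 >= means[2] - 1e-6

    def test_ten_percent_noise_costs_at_most_five_points(self, table):
        fitted = train_svm(table, include_surface=True, seed=4)
        accs = [noise_robustness(fitted, 0.1, seed=s).accuracy
                for s in range(10)]
        assert fitted.report.accuracy - np.mean(accs) <= 0.05

    def test_negative_noise_rejected(self, table):
        fitted = train_svm(table, include_surface=True, seed=4)
        with pytest.raises(ValueError):
            noise_robustness(fitted, -0.1)


class TestDistributionSummaries:
    def test_identical_groups_identical_summaries(self, table):
        half = table.head(1000).copy()
        t = pd.concat([half.assign(label="a"), half.assign(label="b")],
                      ignore_index=True)
        s = group_parameter_stats(t)
        a = s[s["group"] == "a"].drop(columns=["group", "n"]).reset_index(drop=True)
        b = s[s["group"] == "b"].drop(columns=["group", "n"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_tethering_group_has_lower_cv(self, table):
        s = group_parameter_stats(table)
        med = s.set_index(["group", "parameter"])["median"]
        assert med[("tethering", "cv_max")] < med[("normal", "cv_max")]

    def test_single_value_group_zero_iqr(self):
        t = pd.DataFrame({"label": ["x"], "cv_max": [60.0], "apd_max": [80.0]})
        s = group_parameter_stats(t)
        assert (s["q3"] - s["q1"] == 0).all()


class TestKde:
    def test_bandwidth_equals_sample_sd(self):
        """Density for {0,0,0,10} equals the mixture of N(x_i, sd=5)."""
        vals = np.array([0.0, 0.0, 0.0, 10.0])
        grid = np.linspace(-20, 30, 400)
        _, dens = kde_distribution(vals, grid=grid)
        sd = 5.0
        manual = np.mean(
            [np.exp(-0.5 * ((grid - x) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
             for x in vals], axis=0)
        assert np.allclose(dens, manual, atol=1e-6)

    def test_curve_integrates_to_one(self, rng):
        vals = rng.normal(100.0, 20.0, size=200)
        g, d = kde_distribution(vals)
        assert np.trapezoid(d, g) == pytest.approx(1.0, abs=1e-3)

    def test_translation_equivariance(self, rng):
        vals = rng.normal(size=50)
        g1, d1 = kde_distribution(vals, grid=np.linspace(-6, 6, 300))
        g2, d2 = kde_distribution(vals + 10.0, grid=np.linspace(4, 16, 300))
        assert np.allclose(d1, d2, atol=1e-9)

    def test_zero_variance_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="bandwidth"):
            g, d = kde_distribution([3.0, 3.0, 3.0])
        assert np.trapezoid(d, g) == pytest.approx(1.0, abs=1e-3)
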