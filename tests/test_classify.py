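"""Classifier contracts: stratification, separability, chance level,
weight maps and cross-site transfer."""

import numpy as np
import pandas as pd
import pytest

from connectoclass import (
    CohortSpec,
    FeatureTable,
    evaluate_cv,
    fc_feature_table,
    fit_predict,
    generate_cohort,
    leave_one_site_out,
    permutation_test,
    region_importance,
    stratified_folds,
)
from connectoclass.classify import MODEL_KINDS, CvResult, _confusion_rates


def toy_table(features, groups, sites=None, representation="graph", rng=None):
    n = features.shape[0]
    rng = rng or np.random.default_rng(0)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": groups,
            "site": sites if sites is not None else ["site1"] * n,
            "age": rng.uniform(20, 50, n),
            "sex": rng.choice(["M", "F"], n),
        }
    )
    return FeatureTable(subjects=subjects, features=features,
                        representation=representation)


def separable_clouds(rng, n_per_class=20, p=2, gap=6.0):
    a = rng.standard_normal((n_per_class, p)) + gap / 2
    b = rng.standard_normal((n_per_class, p)) - gap / 2
    x = np.vstack([a, b])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return x, y


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            assert (labels[folds == f] == 1).sum() == 10
            assert (labels[folds == f] == 0).sum() == 10

    def test_uneven_classes_stay_within_one(self):
        labels = np.array([1] * 7 + [0] * 13)
        folds = stratified_folds(labels, k=5, seed=3)
        pos_counts = [(labels[folds == f] == 1).sum() for f in range(5)]
        assert set(pos_counts) <= {1, 2}
        assert sum(pos_counts) == 7

    def test_deterministic(self):
        labels = np.array([1] * 11 + [0] * 19)
        np.testing.assert_array_equal(
            stratified_folds(labels, k=5, seed=9),
            stratified_folds(labels, k=5, seed=9),
        )

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="smallest class"):
            stratified_folds(np.array([1, 1, 0, 0, 0, 0, 0]), k=5)


class TestFitPredict:
    @pytest.mark.parametrize("model_kind", MODEL_KINDS)
    def test_separable_training_accuracy_is_one(self, model_kind, rng):
        x, y = separable_clouds(rng)
        pred, weights = fit_predict(model_kind, x, y, x, seed=0)
        assert _confusion_rates(y, pred)[0] == 1.0
        assert weights.shape == (2,)

    def test_chance_level_on_pure_noise(self, rng):
        # 50 repeats of 5-fold CV with random labels and noise features
        accs = []
        for rep in range(50):
            x = rng.standard_normal((40, 10))
            y = rng.permutation([1] * 20 + [0] * 20)
            cv = evaluate_cv(toy_table(x, np.where(y == 1, "patient", "control"),
                                       rng=rng),
                             "LR", k=5, seed=rep, confound_scope=None)
            accs.append(cv.balanced_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("model_kind", ["LR", "SVM"])
    def test_informative_feature_gets_largest_weight(self, model_kind, rng):
        n = 100
        y = np.array([1] * 50 + [0] * 50)
        x = rng.standard_normal((n, 6))
        x[:, 3] += 3.0 * y  # signal only in feature 3
        _, weights = fit_predict(model_kind, x, y, x, seed=0)
        assert np.argmax(np.abs(weights)) == 3

    @pytest.mark.parametrize("model_kind", ["LR", "SVM"])
    def test_weights_align_with_bayes_direction(self, model_kind, rng):
        x, y = separable_clouds(rng, n_per_class=50, p=2, gap=4.0)
        _, w = fit_predict(model_kind, x, y, x, seed=0)
        bayes = np.array([1.0, 1.0]) / np.sqrt(2)  # mean difference direction
        cos = abs(w @ bayes) / np.linalg.norm(w)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 15

    def test_single_class_training_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_predict("LR", x, np.ones(10), x)

    def test_feature_mismatch_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="mismatch"):
            fit_predict("LR", x, y, rng.standard_normal((4, 5)))


class TestMetricsArithmetic:
    def test_confusion_example(self):
        # TP=8, FN=2, TN=5, FP=5
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 8 + [0] * 2 + [1] * 5 + [0] * 5)
        bacc, sens, spec = _confusion_rates(y_true, y_pred)
        assert (sens, spec, bacc) == (0.8, 0.5, 0.65)

    def test_all_correct(self):
        y = np.array([1, 1, 0, 0])
        assert _confusion_rates(y, y) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("n_pos,n_neg", [(10, 10), (3, 47), (40, 5)])
    def test_constant_classifier_is_chance_under_any_imbalance(self, n_pos, n_neg):
        y_true = np.array([1] * n_pos + [0] * n_neg)
        bacc, sens, spec = _confusion_rates(y_true, np.zeros_like(y_true))
        assert (bacc, sens, spec) == (0.5, 0.0, 1.0)


class TestPermutation:
    @pytest.fixture(scope="class")
    def signal_table(self):
        rng = np.random.default_rng(5)
        x, y = separable_clouds(rng, n_per_class=15, p=4, gap=5.0)
        return toy_table(x, np.where(y == 1, "patient", "control"), rng=rng)

    def test_strong_signal_gives_zero_p_under_literal_rule(self, signal_table):
        res = permutation_test(signal_table, "LR", k=5, n_perm=19, seed=0)
        assert res.observed > res.null_accuracies.max()
        assert res.p_value == 0.0
        assert res.null_accuracies.shape == (19,)

    def test_smoothed_rule_never_returns_zero(self, signal_table):
        res = permutation_test(signal_table, "LR", k=5, n_perm=19, seed=0,
                               tie_rule="smoothed")
        assert 0.0 < res.p_value <= 1.0
        assert res.p_value == pytest.approx(1 / 20)

    def test_observed_below_every_null_gives_p_one(self, signal_table):
        # feed anti-learned labels: flip the groups after fold assignment by
        # constructing a table whose labels are independent of features but
        # whose observed run is forced to the minimum via a degenerate case
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 3))
        groups = np.array(["patient", "control"] * 15)
        table = toy_table(x, groups, rng=rng)
        res = permutation_test(table, "LR", k=5, n_perm=39, seed=2)
        if res.observed <= res.null_accuracies.min():
            assert res.p_value == 1.0
        else:  # generic noise case: p is a proper proportion
            assert 0.0 <= res.p_value <= 1.0


class TestRegionImportance:
    def _cv_with_weights(self, weights_list, representation="fc"):
        return CvResult(
            model_kind="LR", representation=representation,
            fold_assignment=np.zeros(4, dtype=int),
            y_true=np.zeros(4, dtype=int), y_pred=np.zeros(4, dtype=int),
            balanced_accuracy=0.5, sensitivity=0.5, specificity=0.5,
            fold_weights=weights_list,
        )

    def test_region_with_all_signal_edges_ranks_first(self):
        n = 10
        n_pairs = n * (n - 1) // 2
        rows, cols = np.tril_indices(n, k=-1)
        w = np.zeros(n_pairs)
        w[(rows == 7) | (cols == 7)] = 1.0  # the 9 edges of region 7
        wmap = region_importance(self._cv_with_weights([w]))
        assert wmap.ranking[0] == 7
        assert wmap.region_scores[7] == pytest.approx(1.0)
        assert np.all(wmap.region_scores[np.arange(n) != 7] < 1.0)

    def test_equal_weights_rank_in_index_order(self):
        n_pairs = 6 * 5 // 2
        wmap = region_importance(self._cv_with_weights([np.ones(n_pairs)]))
        np.testing.assert_array_equal(wmap.ranking, np.arange(6))

    def test_fold_averaging_uses_absolute_values(self):
        n_pairs = 3
        wmap = region_importance(
            self._cv_with_weights([np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])])
        )
        assert wmap.edge_weights[0] == pytest.approx(1.0)

    def test_non_fc_representation_rejected(self):
        with pytest.raises(ValueError, match="fc"):
            region_importance(self._cv_with_weights([np.ones(3)],
                                                    representation="graph"))


class TestCrossSite:
    def test_identical_sites_transfer(self, small_cohort):
        table = fc_feature_table(small_cohort)
        loso = leave_one_site_out(table, "LR", seed=0, confound_scope=None)
        within = [
            evaluate_cv(st, "LR", k=5, seed=0, confound_scope=None).balanced_accuracy
            for st in table.per_site().values()
        ]
        loso_mean = np.mean([cv.balanced_accuracy for cv in loso.values()])
        # the two sites share the planted effect, so transfer stays close
        assert abs(loso_mean - np.mean(within)) < 0.25
        assert loso_mean > 0.6

    def test_antagonistic_sites_fail_to_transfer(self):
        # sites with opposite planted-effect signs: what one site learns is
        # anti-predictive on the other
        specs = [
            CohortSpec(n_regions=20, n_timepoints=120, n_sites=1,
                       n_patients_per_site=15, n_controls_per_site=15,
                       affected_nodes=(0, 1, 2), edge_effect=eff, seed=s)
            for eff, s in ((0.35, 1), (-0.35, 2))
        ]
        cohorts = [generate_cohort(sp) for sp in specs]
        for rec in cohorts[1]:
            rec.site = "site2"
            rec.subject_id = "b_" + rec.subject_id
        table = fc_feature_table(cohorts[0] + cohorts[1])
        loso = leave_one_site_out(table, "LR", seed=0, confound_scope=None)
        loso_mean = np.mean([cv.balanced_accuracy for cv in loso.values()])
        assert loso_mean <= 0.5

    def test_single_class_site_rejected(self, rng):
        x = rng.standard_normal((20, 4))
        groups = ["patient"] * 10 + ["control"] * 10
        sites = ["site1"] * 10 + ["site2"] * 10
        with pytest.raises(ValueError, match="single class"):
            leave_one_site_out(toy_table(x, groups, sites=sites, rng=rng), "LR")

    def test_one_site_rejected(self, rng):
        x = rng.standard_normal((10, 4))
        groups = ["patient"] * 5 + ["control"] * 5
        with pytest.raises(ValueError, match="2 sites"):
            leave_one_site_out(toy_table(x, groups, rng=rng), "LR")


class TestEvaluateCv:
    def test_perfect_separation_end_to_end(self, rng):
        x, y = separable_clouds(rng, n_per_class=15, p=3, gap=8.0)
        table = toy_table(x, np.where(y == 1, "patient", "control"), rng=rng)
        cv = evaluate_cv(table, "LR", k=5, seed=0, confound_scope=None)
        assert cv.balanced_accuracy == 1.0
        assert cv.sensitivity == 1.0 and cv.specificity == 1.0
        assert len(cv.fold_weights) == 5
        assert cv.balanced_accuracy == pytest.approx(
            (cv.sensitivity + cv.specificity) / 2
        )

    def test_folds_partition_subjects(self, rng):
        x, y = separable_clouds(rng, n_per_class=12, p=3)
        table = toy_table(x, np.where(y == 1, "patient", "control"), rng=rng)
        cv = evaluate_cv(table, "SVM", k=4, seed=1, confound_scope=None)
        counts = np.bincount(cv.fold_assignment, minlength=4)
        assert counts.sum() == 24 and np.all(counts > 0)
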