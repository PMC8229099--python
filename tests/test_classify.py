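import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from methylclass import classify
from methylclass.classify import (
    ModelSpec,
    OneVsRestEnsemble,
    compare_models_wilcoxon,
    default_model_bank,
    evaluate_predictions,
    fit_final,
    median_impute,
    nested_cv_select,
    permutation_test,
    predict_subtypes,
)

from conftest import make_beta

FAST_BANK = [
    ModelSpec("nearest centroid", {"shrink_threshold": [None]}),
    ModelSpec("logistic regression", {"C": [1.0]}),
    ModelSpec("decision tree", {"max_depth": [None, 3]}),
]


def separable_beta(n_per=12, n_cpgs=20, seed=0):
    rng = np.random.default_rng(seed)
    values = np.full((n_cpgs, 2 * n_per), 0.2)
    values[:, n_per:] = 0.8
    values += rng.normal(0, 0.02, values.shape)
    beta = make_beta(np.clip(values, 0, 1))
    labels = ["a"] * n_per + ["b"] * n_per
    return beta, labels


class TestModelSpec:
    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown model family"):
            ModelSpec("quantum forest", {"x": [1]})

    def test_empty_grid(self):
        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec("random forest", {})

    def test_default_bank_has_nine_families(self):
        assert len(default_model_bank()) == 9


class TestMedianImpute:
    def test_median_of_two(self):
        train = make_beta(np.array([[0.2, np.nan, 0.4]]))
        out, _ = median_impute(train, train)
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_no_missing_unchanged(self, small_beta):
        a, b = median_impute(small_beta, small_beta)
        assert a.data.equals(small_beta.data)
        assert b.data.equals(small_beta.data)

    def test_train_only_statistic(self):
        train = make_beta(np.array([[0.7, 0.7, 0.7]]))
        apply_to = make_beta(np.array([[0.1, np.nan, 0.2]]),
                             sample_ids=["x", "y", "z"])
        _, filled = median_impute(train, apply_to)
        assert filled.values[0, 1] == pytest.approx(0.7)

    def test_all_missing_cpg_errors(self):
        train = make_beta(np.array([[np.nan, np.nan]]))
        with pytest.raises(ValueError, match="entirely missing"):
            median_impute(train, train)


class TestNestedCvSelect:
    def test_separable_best_is_perfect(self):
        # [DERIVED] wide-margin two-class fixture
        beta, labels = separable_beta()
        report = nested_cv_select(beta, labels, FAST_BANK, outer_k=3,
                                  inner_k=2, seed=0)
        assert report.family_results[report.best_family].mean_accuracy == 1.0

    def test_null_accuracy_near_chance(self):
        # [DERIVED] shuffled labels, 2 balanced classes of 50
        rng = np.random.default_rng(1)
        beta = make_beta(rng.uniform(0, 1, size=(30, 100)))
        labels = rng.permutation(["a"] * 50 + ["b"] * 50)
        report = nested_cv_select(
            beta, labels, [FAST_BANK[0]], outer_k=5, inner_k=2, seed=1)
        assert abs(report.family_results["nearest centroid"].mean_accuracy
                   - 0.5) <= 0.15

    def test_structure(self):
        beta, labels = separable_beta()
        report = nested_cv_select(beta, labels, FAST_BANK, outer_k=4,
                                  inner_k=2, seed=2)
        for result in report.family_results.values():
            assert len(result.outer_accuracies) == 4
            assert len(result.chosen_params) == 4

    def test_small_class_excluded_with_warning(self):
        beta, labels = separable_beta()
        labels = list(labels)
        labels[0] = "singleton"
        with pytest.warns(UserWarning, match="excluded"):
            report = nested_cv_select(beta, labels, [FAST_BANK[0]],
                                      outer_k=3, inner_k=2, seed=0)
        assert report.best_family == "nearest centroid"

    def test_validation_labels_cannot_leak(self):
        # poisoned-label check: with a fixed split, fitted predictions are
        # identical whatever the validation labels are
        from sklearn.model_selection import StratifiedKFold

        beta, labels = separable_beta()
        x = beta.values.T
        y = np.asarray(labels)
        tr, va = next(StratifiedKFold(3, shuffle=True,
                                      random_state=0).split(x, y))
        spec = FAST_BANK[1]
        preds = []
        for poison in (y.copy(), None):
            y_used = y.copy()
            if poison is None:
                y_used[va] = np.random.default_rng(5).permutation(y_used[va])
            params = classify._inner_grid_search(x[tr], y_used[tr], spec,
                                                 2, 0)
            med = classify._fit_medians(x[tr])
            clf = OneVsRestEnsemble(spec, params, 0)
            clf.fit(classify._apply_medians(x[tr], med), y_used[tr])
            preds.append(clf.predict(classify._apply_medians(x[va], med)))
        assert (preds[0] == preds[1]).all()


class TestWilcoxon:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = compare_models_wilcoxon([0.9] * 5, [0.9] * 5)
        assert p == 1.0

    def test_consistent_direction_five_folds(self):
        # [DERIVED] enumerate 2^5 sign assignments: min two-sided p = 2/32
        a = [0.9, 0.91, 0.92, 0.93, 0.94]
        b = [0.8, 0.81, 0.82, 0.83, 0.84]
        _, p = compare_models_wilcoxon(a, b)
        n = 5
        ranks = np.arange(1, n + 1)
        total = ranks.sum()
        null = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=n)]
        observed_w = min(total, 0)  # all positive -> W- = 0
        extreme = sum(1 for w in null if min(w, total - w) <= observed_w)
        assert p == pytest.approx(extreme / 2 ** n) == pytest.approx(0.0625)

    def test_single_fold_errors(self):
        with pytest.raises(ValueError):
            compare_models_wilcoxon([1.0], [0.9])

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.random(30)
        b = a + rng.normal(0.1, 0.05, 30)  # consistent shift
        stat, p = compare_models_wilcoxon(a, b)
        assert p < 1e-4
        from scipy import stats as sps
        ref = sps.wilcoxon(a, b, zero_method="wilcox", method="approx")
        assert p == pytest.approx(ref.pvalue)


class TestFitFinalPredict:
    def test_interpolating_family_training_accuracy(self):
        beta, labels = separable_beta()
        model = fit_final(beta, labels, ModelSpec("decision tree",
                                                  {"max_depth": [None]}))
        preds = predict_subtypes(model, beta)
        assert (preds["label"].to_numpy() == np.asarray(labels)).all()

    def test_single_class_errors(self, small_beta):
        with pytest.raises(ValueError, match="single class"):
            fit_final(small_beta, ["a"] * small_beta.n_samples,
                      FAST_BANK[0])

    def test_deterministic(self):
        beta, labels = separable_beta()
        spec = ModelSpec("random forest", {"n_estimators": [30]})
        p1 = predict_subtypes(fit_final(beta, labels, spec, seed=3), beta)
        p2 = predict_subtypes(fit_final(beta, labels, spec, seed=3), beta)
        pd.testing.assert_frame_equal(p1, p2)

    def test_centroid_sample_predicted_to_its_class(self):
        beta, labels = separable_beta()
        model = fit_final(beta, labels, FAST_BANK[0])
        centroid = beta.data.loc[:, [l == "a" for l in labels]].mean(axis=1)
        query = make_beta(centroid.to_numpy()[:, None],
                          cpg_ids=beta.cpg_ids, sample_ids=["q"])
        preds = predict_subtypes(model, query)
        assert preds.loc[0, "label"] == "a"

    def test_probabilities_sum_to_one(self):
        beta, labels = separable_beta()
        for spec in default_model_bank(small=True):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_final(beta, labels, spec, seed=0)
                preds = predict_subtypes(model, beta)
            totals = preds[["p_a", "p_b"]].sum(axis=1)
            np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_suspected_flag_matches_threshold(self):
        beta, labels = separable_beta()
        model = fit_final(beta, labels, FAST_BANK[1])
        preds = predict_subtypes(model, beta)
        assert (preds["suspected"] == (preds["probability"] >= 0.8)).all()

    def test_missing_cpgs_error(self):
        beta, labels = separable_beta()
        model = fit_final(beta, labels, FAST_BANK[0])
        with pytest.raises(ValueError, match="lacks training CpGs"):
            predict_subtypes(model, make_beta(np.full((2, 2), 0.5)))

    def test_predicted_labels_subset_of_training(self):
        beta, labels = separable_beta()
        model = fit_final(beta, labels, FAST_BANK[0])
        rng = np.random.default_rng(0)
        query = make_beta(rng.uniform(0, 1, (beta.n_cpgs, 5)),
                          cpg_ids=beta.cpg_ids)
        preds = predict_subtypes(model, query)
        assert set(preds["label"]) <= {"a", "b"}


class TestEvaluatePredictions:
    def test_perfect(self):
        ev = evaluate_predictions(["a", "b", "a"], ["a", "b", "a"],
                                  ["a", "b"])
        assert ev.accuracy == 1.0
        assert np.trace(ev.confusion.to_numpy()) == 3
        assert (ev.per_class[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_thirty_of_thirtythree(self):
        # overall accuracy 30/33 = 0.909...
        true = ["a"] * 17 + ["b"] * 16
        pred = ["a"] * 17 + ["b"] * 13 + ["a"] * 3
        ev = evaluate_predictions(pred, true, ["a", "b"])
        assert ev.accuracy == pytest.approx(30 / 33)

    def test_one_sided_predictions(self):
        true = ["a"] * 5 + ["b"] * 5
        with pytest.warns(UserWarning, match="undefined"):
            ev = evaluate_predictions(["a"] * 10, true, ["a", "b"])
        per = ev.per_class.set_index("class")
        assert per.loc["a", "recall"] == 1.0
        assert per.loc["b", "recall"] == 0.0
        assert per.loc["b", "precision"] == 0.0

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="outside class_order"):
            evaluate_predictions(["c"], ["a"], ["a", "b"])

    def test_confusion_total_and_micro_recall(self):
        # micro-averaged recall equals overall accuracy (brute force)
        rng = np.random.default_rng(8)
        classes = ["x", "y", "z"]
        for _ in range(20):
            true = rng.choice(classes, 30)
            pred = rng.choice(classes, 30)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ev = evaluate_predictions(pred, true, classes)
            assert ev.confusion.to_numpy().sum() == 30
            correct = sum(t == p for t, p in zip(true, pred))
            per = ev.per_class.set_index("class")
            micro = sum(per.loc[c, "recall"] * per.loc[c, "support"]
                        for c in classes) / 30
            assert micro == pytest.approx(correct / 30)
            assert ev.accuracy == pytest.approx(correct / 30)


class TestPermutationTest:
    def test_perfect_separation_minimal_p(self):
        beta, labels = separable_beta()
        p = permutation_test(beta, labels, FAST_BANK[0], n_permutations=99,
                             outer_k=3, inner_k=2, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_p_bounds(self):
        rng = np.random.default_rng(2)
        beta = make_beta(rng.uniform(0, 1, (10, 20)))
        labels = ["a"] * 10 + ["b"] * 10
        for b in (1, 5):
            p = permutation_test(beta, labels, FAST_BANK[0],
                                 n_permutations=b, outer_k=2, inner_k=2,
                                 seed=3)
            assert 1 / (b + 1) <= p <= 1.0

    def test_zero_permutations_error(self, small_beta):
        with pytest.raises(ValueError):
            permutation_test(small_beta, ["a", "b"] * 5, FAST_BANK[0],
                             n_permutations=0)

    def test_null_p_not_small(self):
        # [DERIVED] labels independent of features -> p rarely small
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            beta = make_beta(rng.uniform(0, 1, (10, 24)))
            labels = rng.permutation(["a"] * 12 + ["b"] * 12)
            p = permutation_test(beta, labels, FAST_BANK[0],
                                 n_permutations=19, outer_k=3, inner_k=2,
                                 seed=rep)
            hits += p > 0.05
        assert hits >= int(0.9 * n_rep) - 2
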