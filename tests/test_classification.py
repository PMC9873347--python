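"""Classifier construction, metric arithmetic, cross-validation mechanics,
leakage guards and the Mann-Whitney screen."""

import numpy as np
import pandas as pd
import pytest

from ehgkit import evaluation as ev

RNG = np.random.default_rng(31)


def _window_table(n_records, windows_per_record, n_features=4, label="P",
                  prefix="r", shift=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_records):
        for w in range(windows_per_record):
            row = {"record_id": f"{prefix}{i}", "label": label,
                   "window_index": w}
            for j in range(n_features):
                row[f"f{j}"] = rng.standard_normal() + shift
            rows.append(row)
    return pd.DataFrame(rows)


def _two_class_pool(n_per_class=10, windows=3, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    p = _window_table(n_per_class, windows, label="P", prefix="p",
                      shift=shift, rng=rng)
    t = _window_table(n_per_class, windows, label="T", prefix="t",
                      shift=0.0, rng=rng)
    return pd.concat([p, t], ignore_index=True)


FEATS = ["f0", "f1", "f2", "f3"]


class TestMetricArithmetic:
    def test_hand_confusion_matrix(self):
        # TP=45, FN=10, TN=50, FP=5
        y_true = np.array(["P"] * 55 + ["T"] * 55)
        y_pred = np.array(["P"] * 45 + ["T"] * 10 + ["T"] * 50 + ["P"] * 5)
        m = ev.compute_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(95 / 110, abs=1e-4)
        assert m.sensitivity == pytest.approx(45 / 55, abs=1e-4)
        assert m.specificity == pytest.approx(50 / 55, abs=1e-4)
        assert m.ppv == pytest.approx(0.9, abs=1e-4)
        assert m.npv == pytest.approx(50 / 60, abs=1e-4)
        assert m.f_score == pytest.approx(2 * 0.9 * (45 / 55)
                                          / (0.9 + 45 / 55), abs=1e-4)
        assert m.precision == m.ppv
        assert m.recall == m.sensitivity

    def test_perfect_and_random_auc(self):
        y = np.array(["T"] * 50 + ["P"] * 50)
        scores = np.arange(100, dtype=float)
        assert ev.compute_metrics(y, y, scores).auc == pytest.approx(1.0)
        rng = np.random.default_rng(8)
        aucs = [ev.compute_metrics(y, y, rng.uniform(size=100)).auc
                for _ in range(50)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_zero_denominator_warns_and_nans(self):
        y_true = np.array(["T", "T", "T"])
        y_pred = np.array(["T", "T", "T"])
        with pytest.warns(UserWarning, match="sensitivity"):
            m = ev.compute_metrics(y_true, y_pred)
        assert np.isnan(m.sensitivity)
        assert m.specificity == 1.0
        assert m.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ev.compute_metrics(np.array(["P"]), np.array(["P", "T"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_identities_on_random_confusion_matrices(self, seed):
        """acc = (TP+TN)/N; F = harmonic mean of PPV and sensitivity;
        sens/spec complement the error rates of each class."""
        rng = np.random.default_rng(seed)
        tp, fn, tn, fp = rng.integers(1, 200, size=4)
        y_true = np.array(["P"] * (tp + fn) + ["T"] * (tn + fp))
        y_pred = np.array(["P"] * tp + ["T"] * fn
                          + ["T"] * tn + ["P"] * fp)
        m = ev.compute_metrics(y_true, y_pred)
        n = tp + fn + tn + fp
        assert m.accuracy == pytest.approx((tp + tn) / n, abs=1e-12)
        assert m.f_score == pytest.approx(
            2 / (1 / m.ppv + 1 / m.sensitivity), abs=1e-12)
        assert m.sensitivity == pytest.approx(1 - fn / (tp + fn), abs=1e-12)
        assert m.specificity == pytest.approx(1 - fp / (tn + fp), abs=1e-12)
        assert m.npv == pytest.approx(tn / (tn + fn), abs=1e-12)


class TestClassifierFamilies:
    def test_all_families_train_on_separable_data(self):
        pool = _two_class_pool(shift=4.0)
        X = pool[FEATS].to_numpy()
        y = pool["label"].to_numpy()
        for fam in ev.CLASSIFIER_FAMILIES:
            model = ev.train_classifier(ev.ClassifierSpec(fam, 0), X, y)
            assert np.mean(model.predict(X) == y) >= 0.95, fam

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ev.build_classifier(ev.ClassifierSpec("svm_linear", 0), 4)

    def test_rbf_solves_xor_linear_cannot(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(400, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "P", "T")
        X += rng.normal(0, 0.05, X.shape)
        rbf = ev.train_classifier(
            ev.ClassifierSpec("svm_fine_gaussian", 0), X, y)
        lda = ev.train_classifier(
            ev.ClassifierSpec("discriminant_linear", 0), X, y)
        assert np.mean(rbf.predict(X) == y) > 0.9
        assert np.mean(lda.predict(X) == y) < 0.65

    def test_deterministic_training(self):
        pool = _two_class_pool(shift=1.0)
        X, y = pool[FEATS].to_numpy(), pool["label"].to_numpy()
        for fam in ("bagged_tree", "svm_quadratic"):
            a = ev.train_classifier(ev.ClassifierSpec(fam, 3), X, y).predict(X)
            b = ev.train_classifier(ev.ClassifierSpec(fam, 3), X, y).predict(X)
            np.testing.assert_array_equal(a, b)

    def test_positive_scores_orientation(self):
        pool = _two_class_pool(shift=4.0)
        X, y = pool[FEATS].to_numpy(), pool["label"].to_numpy()
        for fam in ("svm_quadratic", "knn_weighted", "bagged_tree"):
            model = ev.train_classifier(ev.ClassifierSpec(fam, 0), X, y)
            s = ev.positive_scores(model, X)
            assert np.mean(s[y == "P"]) > np.mean(s[y == "T"]), fam


class TestFoldStructure:
    def test_1127_windows_into_23_folds(self):
        folds = ev._fold_indices(1127, 23, np.random.default_rng(0))
        sizes = sorted(len(f) for f in folds)
        assert len(folds) == 23
        assert sum(sizes) == 1127
        # 1127 = 23 * 49: every fold has exactly 49 windows
        assert sizes == [49] * 23

    def test_remainder_spread_over_leading_folds(self):
        folds = ev._fold_indices(25, 4, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [6, 6, 6, 7]
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(25))


class TestCrossValidation:
    def test_separable_data_high_accuracy(self):
        pool = _two_class_pool(n_per_class=8, windows=3, shift=4.0)
        test = _two_class_pool(n_per_class=3, windows=3, shift=4.0, seed=9)
        test["record_id"] = "x" + test["record_id"]
        cv = ev.kfold_cross_validate(pool, test, FEATS,
                                     ev.ClassifierSpec("svm_quadratic", 0),
                                     k=8, seed=0)
        assert cv.mean("test", "accuracy") >= 0.9
        assert len(cv.per_fold["test"]) == 8

    def test_record_leakage_raises(self):
        pool = _two_class_pool()
        test = pool.iloc[:6].copy()  # shares record ids with the pool
        with pytest.raises(ev.LeakageError, match="pool and test"):
            ev.kfold_cross_validate(pool, test, FEATS,
                                    ev.ClassifierSpec("svm_quadratic", 0),
                                    k=5, seed=0)

    def test_pool_smaller_than_k_rejected(self):
        pool = _two_class_pool(n_per_class=2, windows=1)
        test = _two_class_pool(n_per_class=2, windows=1, seed=5)
        test["record_id"] = "x" + test["record_id"]
        with pytest.raises(ValueError, match="smaller than k"):
            ev.kfold_cross_validate(pool, test, FEATS,
                                    ev.ClassifierSpec("svm_quadratic", 0),
                                    k=23, seed=0)

    def test_deterministic_given_seed(self):
        pool = _two_class_pool(shift=0.5)
        test = _two_class_pool(n_per_class=3, shift=0.5, seed=9)
        test["record_id"] = "x" + test["record_id"]
        spec = ev.ClassifierSpec("discriminant_linear", 0)
        a = ev.kfold_cross_validate(pool, test, FEATS, spec, k=6, seed=4)
        b = ev.kfold_cross_validate(pool, test, FEATS, spec, k=6, seed=4)
        assert a.mean("validation", "accuracy") == \
            b.mean("validation", "accuracy")

    def test_summary_shape(self):
        pool = _two_class_pool(shift=2.0)
        test = _two_class_pool(n_per_class=3, shift=2.0, seed=9)
        test["record_id"] = "x" + test["record_id"]
        cv = ev.kfold_cross_validate(pool, test, FEATS,
                                     ev.ClassifierSpec("knn_weighted", 0),
                                     k=5, seed=0)
        s = cv.summary()
        assert set(s["split"]) == {"train", "validation", "test"}
        assert {"mean", "sd"} <= set(s.columns)


class TestMannWhitney:
    def test_exact_small_sample_p(self):
        # maximal separation of 3 vs 3 distinct values: two-sided p = 0.1
        df = pd.DataFrame({"RMS": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        labels = np.array(["P"] * 3 + ["T"] * 3)
        out = ev.mann_whitney_screen(df, labels, ["RMS"])
        assert out.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)
        assert out.loc[0, "stars"] == ""

    def test_constant_feature_p_one(self):
        df = pd.DataFrame({"RMS": np.ones(10)})
        labels = np.array(["P"] * 5 + ["T"] * 5)
        out = ev.mann_whitney_screen(df, labels, ["RMS"])
        assert out.loc[0, "p_value"] == 1.0

    def test_shifted_gaussians_four_stars(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"RMS": np.concatenate(
            [rng.standard_normal(100) + 3.0, rng.standard_normal(100)])})
        labels = np.array(["P"] * 100 + ["T"] * 100)
        out = ev.mann_whitney_screen(df, labels, ["RMS"])
        assert out.loc[0, "stars"] == "****"

    def test_star_thresholds(self):
        assert ev.star_code(0.2) == ""
        assert ev.star_code(0.04) == "*"
        assert ev.star_code(0.005) == "**"
        assert ev.star_code(0.0005) == "***"
        assert ev.star_code(0.00005) == "****"
        assert ev.star_code(0.05) == ""  # strict inequality

    def test_needs_two_classes_and_min_windows(self):
        df = pd.DataFrame({"RMS": np.ones(4)})
        with pytest.raises(ValueError, match="two classes"):
            ev.mann_whitney_screen(df, np.array(["P"] * 4), ["RMS"])
        with pytest.raises(ValueError, match="at least 3"):
            ev.mann_whitney_screen(df, np.array(["P", "P", "T", "T"]),
                                   ["RMS"])
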