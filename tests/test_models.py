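"""Model training, cross-validation, tuning, importance, metric arithmetic."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from gquadfold.features import SELECTED_FEATURES
from gquadfold.models import (
    ModelBundle,
    SchemaMismatchError,
    evaluate_predictions,
    feature_importance,
    train_classifier,
    train_regressor,
    tune_hyperparameters,
)


def _separable_table(n=400, seed=0) -> pd.DataFrame:
    """Folding label is a clean threshold on G frequency."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {name: rng.random(n) for name in SELECTED_FEATURES}
    )
    table["folded"] = table["freq_G"] > 0.5
    table["energy"] = -30.0 * table["freq_G"] - 2.0 * table["n_tetrads"]
    return table


class TestTrainClassifier:
    def test_separable_set_is_learned(self):
        bundle = train_classifier(_separable_table(), "xgboost", seed=1)
        assert bundle.cv_report.mean["accuracy"] >= 0.99

    def test_permuted_labels_have_chance_auroc(self):
        table = _separable_table(n=2000, seed=2)
        rng = np.random.default_rng(3)
        table["folded"] = rng.permutation(table["folded"].to_numpy())
        bundle = train_classifier(table, "xgboost", seed=2)
        assert bundle.cv_report.mean["auroc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_labels_rejected(self):
        table = _separable_table(n=50)
        table["folded"] = True
        with pytest.raises(ValueError, match="single class"):
            train_classifier(table, "xgboost")

    def test_nan_features_rejected(self):
        table = _separable_table(n=50)
        table.loc[3, "freq_G"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_classifier(table, "xgboost")

    def test_missing_columns_named(self):
        table = _separable_table(n=50).drop(columns=["di_GG", "di_CC"])
        with pytest.raises(SchemaMismatchError, match="di_GG"):
            train_classifier(table, "xgboost")

    @pytest.mark.parametrize("algorithm", ["random_forest", "logistic", "naive_bayes"])
    def test_alternative_algorithms_run(self, algorithm):
        bundle = train_classifier(_separable_table(n=200), algorithm, seed=0)
        assert bundle.cv_report.n_folds == 5
        assert 0 <= bundle.cv_report.mean["f1"] <= 1

    def test_fixed_seed_reports_are_bit_identical(self):
        table = _separable_table(n=300, seed=5)
        r1 = train_classifier(table, "xgboost", seed=9).cv_report
        r2 = train_classifier(table, "xgboost", seed=9).cv_report
        assert r1.folds == r2.folds
        assert r1.roc_curves == r2.roc_curves

    def test_f1_is_harmonic_mean_per_fold(self, labeled_table):
        bundle = train_classifier(labeled_table, "xgboost", seed=3)
        for fold_metrics in bundle.cv_report.folds:
            p, r = fold_metrics["precision"], fold_metrics["recall"]
            assert fold_metrics["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-9)


class TestTrainRegressor:
    def test_noiseless_linear_target_is_recovered(self):
        bundle = train_regressor(_separable_table(n=600), "xgboost", seed=1)
        assert bundle.cv_report.mean["r2"] >= 0.95

    def test_constant_target_yields_defined_metrics(self):
        table = _separable_table(n=100)
        table["energy"] = -5.0
        bundle = train_regressor(table, "xgboost", seed=1)
        assert bundle.cv_report.mean["rmse"] == pytest.approx(0.0, abs=1e-3)
        assert np.isfinite(bundle.cv_report.mean["r2"])

    def test_report_serializes_to_json(self, tmp_path):
        bundle = train_regressor(_separable_table(n=100), "xgboost", seed=1)
        path = tmp_path / "cv.json"
        bundle.cv_report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["task"] == "regression"
        assert len(payload["folds"]) == 5


class TestTuning:
    def test_budget_one_returns_defaults(self):
        table = _separable_table(n=200)
        bundle = tune_hyperparameters(table, "xgboost", budget=1, seed=0)
        assert bundle.hyperparameters == {}

    def test_budget_below_one_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(_separable_table(n=50), "xgboost", budget=0)

    def test_search_never_worse_than_defaults(self, labeled_table):
        default = train_classifier(labeled_table, "xgboost", seed=4)
        tuned = tune_hyperparameters(labeled_table, "xgboost", budget=5, seed=4)
        assert tuned.cv_report.mean["f1"] >= default.cv_report.mean["f1"]

    def test_separable_set_keeps_perfect_f1(self):
        bundle = tune_hyperparameters(_separable_table(), "xgboost", budget=3, seed=0)
        assert bundle.cv_report.mean["f1"] >= 0.99


class TestFeatureImportance:
    def test_informative_feature_dominates_improvement_score(self):
        bundle = train_classifier(_separable_table(n=500), "xgboost", seed=0)
        imp = feature_importance(bundle).set_index("feature")
        assert imp["total_squared_improvement"].idxmax() == "freq_G"
        assert imp.loc["freq_G", "split_count"] > 0
        # aliases follow the split-count-as-gain convention
        assert (imp["gain"] == imp["split_count"]).all()
        assert (imp["weight"] == imp["total_squared_improvement"]).all()

    def test_covers_every_feature_with_nonnegative_scores(self, regressor_bundle):
        imp = feature_importance(regressor_bundle)
        assert list(imp["feature"]) == regressor_bundle.feature_names
        assert (imp["split_count"] >= 0).all()
        assert (imp["total_squared_improvement"] >= 0).all()

    def test_sklearn_tree_models_supported(self):
        bundle = train_classifier(_separable_table(n=200), "random_forest", seed=0)
        imp = feature_importance(bundle).set_index("feature")
        assert imp["split_count"].sum() > 0

    def test_non_tree_model_rejected(self):
        bundle = train_classifier(_separable_table(n=200), "logistic", seed=0)
        with pytest.raises(TypeError, match="tree-based"):
            feature_importance(bundle)


class TestBundle:
    def test_roundtrip_persistence(self, tmp_path):
        bundle = train_classifier(_separable_table(n=200), "xgboost", seed=0)
        path = tmp_path / "clf.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        assert loaded.feature_names == bundle.feature_names
        assert loaded.fingerprint == bundle.fingerprint

    def test_predict_refuses_mismatched_schema(self):
        bundle = train_classifier(_separable_table(n=200), "xgboost", seed=0)
        bad = pd.DataFrame({"freq_G": [0.5]})
        with pytest.raises(SchemaMismatchError):
            bundle.predict(bad)

    def test_threshold_override_at_predict_time(self):
        table = _separable_table(n=300, seed=1)
        bundle = train_classifier(table, "xgboost", seed=0)
        loose = bundle.predict(table, threshold=0.05).sum()
        strict = bundle.predict(table, threshold=0.95).sum()
        assert loose >= strict


class TestEvaluatePredictions:
    def test_perfect_prediction(self):
        m = evaluate_predictions([1, 1, 0], [1, 1, 0])
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_total_misclassification(self):
        assert evaluate_predictions([1, 0], [0, 1])["accuracy"] == 0.0

    def test_xray_style_confusion_counts(self):
        # 72 positives / 6 negatives with 70 true positives and 3 true negatives
        truth = [1] * 72 + [0] * 6
        pred = [1] * 70 + [0] * 2 + [1] * 3 + [0] * 3
        m = evaluate_predictions(truth, pred)
        assert m["accuracy"] == pytest.approx(73 / 78, abs=1e-9)
        assert m["balanced_accuracy"] == pytest.approx((70 / 72 + 3 / 6) / 2, abs=1e-9)
        assert (m["tp"], m["tn"], m["fn"], m["fp"]) == (70, 3, 2, 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([], [])

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 200)
        probs = rng.random(200)
        a = evaluate_predictions(truth, probabilities=probs)["auroc"]
        b = evaluate_predictions(truth, probabilities=np.exp(5 * probs))["auroc"]
        assert a == pytest.approx(b, abs=1e-12)
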