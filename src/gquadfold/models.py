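"""Training, cross-validation, tuning and interrogation of folding models.

Two supervised tasks share one harness: a binary classifier for the
quadruplex folding state (folded / unfolded under the MFE engine's label)
and a regressor for the folding free energy in kcal/mol.  Eight classifier
families and three regressor families are supported; gradient boosting is
the intended production model, the rest exist for benchmarking.  Evaluation
is k-fold cross-validation (stratified for classification, shuffled for
regression) with per-fold metrics, ROC/PR curve points, and a final refit
on the full table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    confusion_matrix,
    explained_variance_score,
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    precision_recall_curve,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier, XGBRegressor

from .features import SELECTED_FEATURES

__all__ = [
    "CLASSIFIER_ALGORITHMS",
    "REGRESSOR_ALGORITHMS",
    "CVReport",
    "ModelBundle",
    "SchemaMismatchError",
    "train_classifier",
    "train_regressor",
    "tune_hyperparameters",
    "feature_importance",
    "evaluate_predictions",
]


class SchemaMismatchError(ValueError):
    """Feature table does not match the schema a bundle was trained on."""


def _factory(cls, **defaults):
    def make(**params):
        return cls(**{**defaults, **params})

    return make


def _classifier_factories(seed: int) -> dict[str, Any]:
    return {
        "xgboost": _factory(
            XGBClassifier,
            n_estimators=200,
            max_depth=6,
            learning_rate=0.3,
            n_jobs=1,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
        ),
        "random_forest": _factory(
            RandomForestClassifier, n_estimators=200, random_state=seed, n_jobs=1
        ),
        "cart": _factory(DecisionTreeClassifier, random_state=seed),
        "neural_net": _factory(
            MLPClassifier, hidden_layer_sizes=(64, 32), max_iter=500, random_state=seed
        ),
        "logistic": _factory(LogisticRegression, max_iter=2000, random_state=seed),
        "lda": _factory(LinearDiscriminantAnalysis),
        "knn": _factory(KNeighborsClassifier),
        "naive_bayes": _factory(GaussianNB),
    }


def _regressor_factories(seed: int) -> dict[str, Any]:
    return {
        "xgboost": _factory(
            XGBRegressor,
            n_estimators=300,
            max_depth=6,
            learning_rate=0.3,
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        ),
        "gradient_boosting": _factory(GradientBoostingRegressor, random_state=seed),
        "neural_net": _factory(
            MLPRegressor, hidden_layer_sizes=(64, 32), max_iter=500, random_state=seed
        ),
    }


CLASSIFIER_ALGORITHMS = tuple(_classifier_factories(0))
REGRESSOR_ALGORITHMS = tuple(_regressor_factories(0))

CLASSIFICATION_METRICS = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "recall",
    "f1",
    "auroc",
)
REGRESSION_METRICS = ("rmse", "r2", "explained_variance", "mae")


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation metrics.

    ``folds`` is a list of metric dicts; ``mean``/``sd`` aggregate them.
    For classification, ``roc_curves`` and ``pr_curves`` hold per-fold point
    lists [(x, y), ...] for external plotting.
    """

    task: str
    n_folds: int
    folds: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    roc_curves: list[list[tuple[float, float]]] = field(default_factory=list)
    pr_curves: list[list[tuple[float, float]]] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "task": self.task,
                "n_folds": self.n_folds,
                "folds": self.folds,
                "mean": self.mean,
                "sd": self.sd,
                "roc_curves": self.roc_curves,
                "pr_curves": self.pr_curves,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class ModelBundle:
    """A trained estimator plus everything needed to apply it safely.

    Prediction refuses feature tables whose columns do not cover the
    training schema, so stale bundles fail loudly rather than silently
    permuting features.
    """

    estimator: Any
    algorithm: str
    task: str  # "classification" | "regression"
    hyperparameters: dict[str, Any]
    feature_names: list[str]
    threshold: float
    cv_report: CVReport
    fingerprint: str
    engine_metadata: dict[str, Any] = field(default_factory=dict)

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise SchemaMismatchError(f"feature table is missing columns: {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("feature table contains NaN values")
        return X

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("probabilities are only defined for classifiers")
        return self.estimator.predict_proba(self._matrix(table))[:, 1]

    def predict(self, table: pd.DataFrame, threshold: Optional[float] = None):
        X = self._matrix(table)
        if self.task == "classification":
            thr = self.threshold if threshold is None else threshold
            return self.estimator.predict_proba(X)[:, 1] >= thr
        return self.estimator.predict(X)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise ValueError(f"{path} does not contain a ModelBundle")
        return bundle


def _fingerprint(table: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(table, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _validate_table(
    table: pd.DataFrame, feature_names: Sequence[str], label_col: str
) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in list(feature_names) + [label_col] if c not in table.columns]
    if missing:
        raise SchemaMismatchError(f"training table is missing columns: {missing}")
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    if np.isnan(X).any():
        raise ValueError("training features contain NaN values")
    return X, y


def _classification_fold_metrics(y_true, y_pred, y_prob) -> dict[str, float]:
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
        "auroc": roc_auc_score(y_true, y_prob),
    }


def _aggregate(folds: list[dict[str, float]]) -> tuple[dict, dict]:
    keys = folds[0].keys()
    mean = {k: float(np.mean([f[k] for f in folds])) for k in keys}
    sd = {k: float(np.std([f[k] for f in folds])) for k in keys}
    return mean, sd


def train_classifier(
    table: pd.DataFrame,
    algorithm: str = "xgboost",
    *,
    folds: int = 5,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    label_col: str = "folded",
    threshold: float = 0.5,
    params: Optional[dict[str, Any]] = None,
    engine_metadata: Optional[dict[str, Any]] = None,
) -> ModelBundle:
    """Stratified k-fold CV then full refit of a folding-state classifier."""
    factories = _classifier_factories(seed)
    if algorithm not in factories:
        raise ValueError(
            f"unknown classifier {algorithm!r}; choose from {sorted(factories)}"
        )
    feature_names = list(feature_names or SELECTED_FEATURES)
    X, y = _validate_table(table, feature_names, label_col)
    y = y.astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")

    params = params or {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics, rocs, prs = [], [], []
    for train_idx, test_idx in cv.split(X, y):
        est = factories[algorithm](**params)
        est.fit(X[train_idx], y[train_idx])
        prob = est.predict_proba(X[test_idx])[:, 1]
        pred = prob >= threshold
        fold_metrics.append(_classification_fold_metrics(y[test_idx], pred, prob))
        fpr, tpr, _ = roc_curve(y[test_idx], prob)
        rocs.append(list(zip(fpr.tolist(), tpr.tolist())))
        prec, rec, _ = precision_recall_curve(y[test_idx], prob)
        prs.append(list(zip(rec.tolist(), prec.tolist())))
    mean, sd = _aggregate(fold_metrics)
    report = CVReport(
        task="classification",
        n_folds=folds,
        folds=fold_metrics,
        mean=mean,
        sd=sd,
        roc_curves=rocs,
        pr_curves=prs,
    )

    final = factories[algorithm](**params)
    final.fit(X, y)
    return ModelBundle(
        estimator=final,
        algorithm=algorithm,
        task="classification",
        hyperparameters=params,
        feature_names=feature_names,
        threshold=threshold,
        cv_report=report,
        fingerprint=_fingerprint(table),
        engine_metadata=engine_metadata or {},
    )


def train_regressor(
    table: pd.DataFrame,
    algorithm: str = "xgboost",
    *,
    folds: int = 5,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    label_col: str = "energy",
    params: Optional[dict[str, Any]] = None,
    engine_metadata: Optional[dict[str, Any]] = None,
) -> ModelBundle:
    """Shuffled k-fold CV then full refit of a folding-energy regressor."""
    factories = _regressor_factories(seed)
    if algorithm not in factories:
        raise ValueError(
            f"unknown regressor {algorithm!r}; choose from {sorted(factories)}"
        )
    feature_names = list(feature_names or SELECTED_FEATURES)
    X, y = _validate_table(table, feature_names, label_col)
    y = y.astype(float)
    if np.isnan(y).any():
        raise ValueError("energy labels contain NaN values")

    params = params or {}
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    for train_idx, test_idx in cv.split(X):
        est = factories[algorithm](**params)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        fold_metrics.append(
            {
                "rmse": float(np.sqrt(mean_squared_error(y[test_idx], pred))),
                "r2": r2_score(y[test_idx], pred),
                "explained_variance": explained_variance_score(y[test_idx], pred),
                "mae": mean_absolute_error(y[test_idx], pred),
            }
        )
    mean, sd = _aggregate(fold_metrics)
    report = CVReport(
        task="regression", n_folds=folds, folds=fold_metrics, mean=mean, sd=sd
    )

    final = factories[algorithm](**params)
    final.fit(X, y)
    return ModelBundle(
        estimator=final,
        algorithm=algorithm,
        task="regression",
        hyperparameters=params,
        feature_names=feature_names,
        threshold=0.5,
        cv_report=report,
        fingerprint=_fingerprint(table),
        engine_metadata=engine_metadata or {},
    )


# Random-search spaces for the gradient-boosted models; other algorithms
# tune nothing beyond their defaults unless a space is supplied.
DEFAULT_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "xgboost": {
        "n_estimators": [100, 200, 300, 500],
        "max_depth": [3, 4, 6, 8],
        "learning_rate": [0.05, 0.1, 0.2, 0.3],
        "subsample": [0.7, 0.85, 1.0],
        "colsample_bytree": [0.7, 0.85, 1.0],
        "min_child_weight": [1, 3, 5],
    },
    "gradient_boosting": {
        "n_estimators": [100, 200, 300],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1, 0.2],
        "subsample": [0.7, 0.85, 1.0],
    },
}


def tune_hyperparameters(
    table: pd.DataFrame,
    algorithm: str = "xgboost",
    *,
    task: str = "classification",
    search_space: Optional[dict[str, list]] = None,
    budget: int = 20,
    folds: int = 5,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    label_col: Optional[str] = None,
) -> ModelBundle:
    """Random-search tuning on fixed CV folds; never worse than defaults.

    Candidates are the default configuration plus ``budget - 1`` random
    draws from the search space; selection is by mean CV F1 (classification)
    or mean CV RMSE (regression) on the same folds.  Returns the bundle
    trained with the winning configuration.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    space = search_space or DEFAULT_SEARCH_SPACES.get(algorithm, {})
    rng = np.random.default_rng(seed)
    candidates: list[dict[str, Any]] = [{}]
    while len(candidates) < budget and space:
        draw = {k: v[rng.integers(len(v))] for k, v in space.items()}
        if draw not in candidates:
            candidates.append(draw)

    train = train_classifier if task == "classification" else train_regressor
    kwargs: dict[str, Any] = {"folds": folds, "seed": seed}
    if feature_names is not None:
        kwargs["feature_names"] = feature_names
    if label_col is not None:
        kwargs["label_col"] = label_col

    best_bundle, best_score = None, None
    for params in candidates:
        bundle = train(table, algorithm, params=params, **kwargs)
        if task == "classification":
            score = bundle.cv_report.mean["f1"]
            better = best_score is None or score > best_score
        else:
            score = bundle.cv_report.mean["rmse"]
            better = best_score is None or score < best_score
        if better:
            best_bundle, best_score = bundle, score
    assert best_bundle is not None
    return best_bundle


def _sklearn_tree_scores(trees, n_features: int) -> tuple[np.ndarray, np.ndarray]:
    splits = np.zeros(n_features)
    improvement = np.zeros(n_features)
    for tree in trees:
        t = tree.tree_
        for node in range(t.node_count):
            f = t.feature[node]
            if f < 0:  # leaf
                continue
            splits[f] += 1
            left, right = t.children_left[node], t.children_right[node]
            n, nl, nr = (
                t.weighted_n_node_samples[node],
                t.weighted_n_node_samples[left],
                t.weighted_n_node_samples[right],
            )
            gain = n * t.impurity[node] - nl * t.impurity[left] - nr * t.impurity[right]
            improvement[f] += max(gain, 0.0)
    return splits, improvement


def feature_importance(bundle: ModelBundle) -> pd.DataFrame:
    """Split-count and total-squared-improvement importance of a tree model.

    Columns ``split_count`` (times a feature is chosen to split a node) and
    ``total_squared_improvement`` (summed loss reduction from those splits)
    are the unambiguous names; ``gain`` and ``weight`` aliases follow the
    convention in which *gain* counts splits and *weight* measures the
    empirical squared improvement — note this is transposed relative to the
    xgboost API's own naming.
    """
    est = bundle.estimator
    names = bundle.feature_names
    if isinstance(est, (XGBClassifier, XGBRegressor)):
        booster = est.get_booster()
        raw_splits = booster.get_score(importance_type="weight")
        raw_gain = booster.get_score(importance_type="total_gain")
        # booster features are f0, f1, ... in training column order
        splits = np.array([raw_splits.get(f"f{i}", 0.0) for i in range(len(names))])
        improvement = np.array([raw_gain.get(f"f{i}", 0.0) for i in range(len(names))])
    elif hasattr(est, "estimators_"):  # random forest / gradient boosting
        trees = np.asarray(est.estimators_).ravel()
        splits, improvement = _sklearn_tree_scores(trees, len(names))
    elif hasattr(est, "tree_"):  # single CART
        splits, improvement = _sklearn_tree_scores([est], len(names))
    else:
        raise TypeError(
            f"feature importance requires a tree-based model, got {type(est).__name__}"
        )
    out = pd.DataFrame(
        {
            "feature": names,
            "split_count": splits,
            "total_squared_improvement": improvement,
        }
    )
    out["gain"] = out["split_count"]
    out["weight"] = out["total_squared_improvement"]
    return out


def evaluate_predictions(
    y_true,
    y_pred=None,
    *,
    probabilities=None,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Classification metrics and confusion counts for label vectors.

    Either *y_pred* or *probabilities* (thresholded at *threshold*) must be
    given; AUROC is included when probabilities are available.
    """
    y_true = np.asarray(y_true).astype(int)
    if y_true.size == 0:
        raise ValueError("empty truth vector")
    if y_pred is None:
        if probabilities is None:
            raise ValueError("provide y_pred or probabilities")
        y_pred = np.asarray(probabilities) >= threshold
    y_pred = np.asarray(y_pred).astype(int)
    if y_pred.shape != y_true.shape:
        raise ValueError("truth and prediction vectors differ in length")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
        "tn": int(tn),
        "fp": int(fp),
        "fn": int(fn),
        "tp": int(tp),
    }
    if probabilities is not None and np.unique(y_true).size == 2:
        out["auroc"] = roc_auc_score(y_true, probabilities)
    return out
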