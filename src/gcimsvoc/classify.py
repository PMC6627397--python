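"""Cross-validated classification with per-fold feature selection.

The design follows the standard leakage-free protocol for small-n, large-p
omics classification: the cohort is split into 10 stratified folds; within
each fold the k most discriminatory features are chosen by rank-sum testing
on the *training* rows only, the classifier is fitted on those rows and
features, and calibrated class probabilities are emitted for the held-out
rows.  Every sample is a test sample exactly once, and the pooled
out-of-fold probabilities feed all downstream ROC analysis.

Five classifier families are supported — sparse (L1) logistic regression,
random forest, Gaussian process, RBF support vector machine with Platt
calibration, and a single-hidden-layer neural net — each behind a common
fit/predict contract.  Features are standardised inside each training fold
(margin- and gradient-based models need comparable scales); hyperparameters
are fixed, documented defaults rather than searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import FeatureMatrix
from .selection import DEFAULT_K, top_k_features

__all__ = ["CLASSIFIER_NAMES", "ClassifierSpec", "CVResult",
           "stratified_folds", "fit_predict_contract",
           "crossval_probabilities"]

CLASSIFIER_NAMES = ("sparse_logistic", "random_forest", "gaussian_process",
                    "svm", "neural_net")

#: Fixed hyperparameter defaults (overridable via ClassifierSpec.params).
DEFAULT_PARAMS = {
    "sparse_logistic": {"C": 1.0, "max_iter": 2000},
    "random_forest": {"n_estimators": 200},
    "gaussian_process": {"length_scale": 1.0},
    "svm": {"C": 1.0, "gamma": "scale"},
    "neural_net": {"hidden_layer_sizes": (32,), "max_iter": 1000,
                   "alpha": 1e-2},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameter overrides for one classifier family."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; "
                f"supported: {CLASSIFIER_NAMES}")

    def resolved_params(self) -> dict:
        return {**DEFAULT_PARAMS[self.name], **self.params}


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities with fold/feature provenance."""

    sample_ids: list
    labels: np.ndarray              # original group labels
    y: np.ndarray                   # 1 = positive class
    probabilities: np.ndarray       # P(positive) from the held-out fold
    fold_ids: np.ndarray
    selected_features: list         # per fold: sorted feature indices
    positive_class: str
    spec: ClassifierSpec
    seed: int


def _build(spec: ClassifierSpec, seed: int, min_class_count: int):
    p = spec.resolved_params()
    if spec.name == "sparse_logistic":
        # pure lasso; large intercept_scaling keeps liblinear's intercept
        # effectively unpenalised
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                 C=p["C"], max_iter=p["max_iter"],
                                 intercept_scaling=100.0,
                                 random_state=seed)
    elif spec.name == "random_forest":
        clf = RandomForestClassifier(n_estimators=p["n_estimators"],
                                     random_state=seed)
    elif spec.name == "gaussian_process":
        clf = GaussianProcessClassifier(kernel=RBF(p["length_scale"]),
                                        random_state=seed)
    elif spec.name == "svm":
        # Platt scaling fitted within the training fold turns SVM margins
        # into probabilities
        base = SVC(kernel="rbf", C=p["C"], gamma=p["gamma"],
                   random_state=seed)
        clf = CalibratedClassifierCV(base, method="sigmoid",
                                     ensemble=False,
                                     cv=min(5, min_class_count))
    elif spec.name == "neural_net":
        clf = MLPClassifier(hidden_layer_sizes=p["hidden_layer_sizes"],
                            max_iter=p["max_iter"], alpha=p["alpha"],
                            random_state=seed)
    return make_pipeline(StandardScaler(), clf)


def fit_predict_contract(spec: ClassifierSpec, X_train, y_train, X_test,
                         seed: int = 0) -> np.ndarray:
    """Fit on training rows, return P(class 1) for test rows.

    Columns are expected to be restricted to the selected features already.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if (not np.all(np.isfinite(X_train))
            or not np.all(np.isfinite(X_test))):
        raise ValueError("features must be finite")
    y_train = np.asarray(y_train).astype(int)
    model = _build(spec, seed, int(np.bincount(y_train).min()))
    model.fit(X_train, y_train)
    proba = model.predict_proba(X_test)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return np.clip(proba[:, pos_col], 0.0, 1.0)


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1) per sample.

    ``k == n`` degrades to a leave-one-out partition (stratification is
    moot for singleton folds).
    """
    labels = np.asarray(labels)
    if k > labels.size:
        raise ValueError(f"k={k} exceeds the {labels.size} samples")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    if k == labels.size:
        return np.arange(labels.size)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    with warnings.catch_warnings():
        # k=10 with a 7-sample minority class is the intended design; some
        # folds simply carry no minority test sample
        warnings.filterwarnings(
            "ignore", message="The least populated class")
        for fold, (_, test_idx) in enumerate(
                skf.split(np.zeros((labels.size, 1)), labels)):
            assignment[test_idx] = fold
    return assignment


def crossval_probabilities(features: FeatureMatrix, labels,
                           spec: ClassifierSpec,
                           positive_class: str,
                           k: int = 10, n_select: int = DEFAULT_K,
                           seed: int = 0) -> CVResult:
    """Out-of-fold probabilities with within-fold feature selection.

    For each of the ``k`` stratified folds: rank features by rank-sum test
    on training rows only, keep the top ``n_select``, fit the classifier on
    those rows/columns, and record calibrated probabilities for the held-out
    rows.
    """
    labels = np.asarray(labels)
    if labels.size != features.n_samples:
        raise ValueError("labels length does not match the feature matrix")
    y = (labels == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"positive class {positive_class!r} must be a strict subset "
            "of the samples")

    fold_ids = stratified_folds(labels, k=k, seed=seed)
    probs = np.full(labels.size, np.nan)
    selected = []
    for fold in range(k):
        test = fold_ids == fold
        train = ~test
        y_train = y[train]
        if y_train.min() == y_train.max():
            raise ValueError(
                f"training set of fold {fold} contains a single class; "
                "use a smaller k")
        ranking = top_k_features(features.values[train], y_train,
                                 k=n_select)
        cols = np.sort(ranking.indices)
        probs[test] = fit_predict_contract(
            spec, features.values[np.ix_(train, cols)], y_train,
            features.values[np.ix_(test, cols)], seed=seed)
        selected.append(cols)

    assert not np.isnan(probs).any()
    return CVResult(sample_ids=list(features.sample_ids), labels=labels,
                    y=y, probabilities=probs, fold_ids=fold_ids,
                    selected_features=selected,
                    positive_class=positive_class, spec=spec, seed=seed)
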