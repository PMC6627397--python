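import numpy as np
import pytest

from gcimsvoc.classify import (ClassifierSpec, crossval_probabilities,
                               fit_predict_contract, stratified_folds)
from gcimsvoc.preprocess import FeatureMatrix


def feature_matrix(X):
    X = np.asarray(X, float)
    return FeatureMatrix(values=X,
                         sample_ids=[f"s{i}" for i in range(X.shape[0])],
                         feature_coords=np.zeros((X.shape[1], 2)),
                         retention_axis=np.arange(1.0),
                         drift_axis=np.arange(float(X.shape[1])))


def gaussian_clouds(n_pos, n_neg, n_features, separation, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, n_features))
    X[:n_pos, :5] += separation
    labels = np.array(["pos"] * n_pos + ["neg"] * n_neg)
    return feature_matrix(X), labels


# ----------------------------------------------------------------- folds

def test_study_design_folds_partition_in_pairs():
    labels = np.array(["CD"] * 13 + ["RCD"] * 7)
    folds = stratified_folds(labels, k=10, seed=1)
    sizes = np.bincount(folds, minlength=10)
    assert sizes.tolist() == [2] * 10
    assert np.sort(np.unique(folds)).tolist() == list(range(10))


def test_folds_near_proportional_class_counts():
    labels = np.array(["a"] * 13 + ["b"] * 7)
    folds = stratified_folds(labels, k=10, seed=3)
    for f in range(10):
        n_b = np.sum((folds == f) & (labels == "b"))
        assert abs(n_b - 0.7) <= 1


def test_leave_one_out_partition():
    labels = np.array(["a", "a", "b", "b", "a"])
    folds = stratified_folds(labels, k=5, seed=0)
    assert sorted(folds.tolist()) == [0, 1, 2, 3, 4]


def test_folds_deterministic_given_seed():
    labels = np.array(["a"] * 8 + ["b"] * 8)
    np.testing.assert_array_equal(stratified_folds(labels, 4, seed=9),
                                  stratified_folds(labels, 4, seed=9))


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        stratified_folds(np.array(["a", "b"]), k=3)


# ----------------------------------------------------------------- contract

@pytest.mark.parametrize("name", ["sparse_logistic", "random_forest",
                                  "gaussian_process", "svm", "neural_net"])
def test_contract_probabilities_in_unit_interval(name):
    fm, labels = gaussian_clouds(8, 8, 10, separation=3.0)
    y = (labels == "pos").astype(int)
    p = fit_predict_contract(ClassifierSpec(name), fm.values[:12], y[:12],
                             fm.values[12:], seed=0)
    assert p.shape == (4,)
    assert np.all((p >= 0) & (p <= 1))


def test_constant_features_give_prevalence_for_sparse_logistic():
    X = np.ones((10, 4))
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    p = fit_predict_contract(ClassifierSpec("sparse_logistic"), X, y,
                             np.ones((3, 4)), seed=0)
    assert p == pytest.approx(np.full(3, 0.3), abs=0.02)


def test_duplicating_training_samples_barely_moves_weakly_penalised_logistic():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 6))
    y = np.array([1] * 6 + [0] * 6)
    X_test = rng.normal(size=(4, 6))
    spec = ClassifierSpec("sparse_logistic", {"C": 1e6})
    a = fit_predict_contract(spec, X, y, X_test, seed=0)
    b = fit_predict_contract(spec, np.vstack([X, X]),
                             np.concatenate([y, y]), X_test, seed=0)
    np.testing.assert_allclose(a, b, atol=1e-3)


@pytest.mark.parametrize("name", ["random_forest", "neural_net", "svm"])
def test_contract_deterministic_under_fixed_seed(name):
    fm, labels = gaussian_clouds(10, 10, 8, separation=1.0, seed=2)
    y = (labels == "pos").astype(int)
    a = fit_predict_contract(ClassifierSpec(name), fm.values[:16], y[:16],
                             fm.values[16:], seed=7)
    b = fit_predict_contract(ClassifierSpec(name), fm.values[:16], y[:16],
                             fm.values[16:], seed=7)
    np.testing.assert_array_equal(a, b)


def test_non_finite_features_rejected():
    X = np.ones((4, 2))
    X[0, 0] = np.inf
    with pytest.raises(ValueError, match="finite"):
        fit_predict_contract(ClassifierSpec("svm"), X, [0, 0, 1, 1],
                             np.ones((1, 2)))


def test_unknown_classifier_rejected():
    with pytest.raises(ValueError, match="unknown classifier"):
        ClassifierSpec("deep_transformer")


# ----------------------------------------------------------------- crossval

def test_separated_clouds_classified_correctly_out_of_fold():
    fm, labels = gaussian_clouds(13, 7, 50, separation=6.0, seed=1)
    cv = crossval_probabilities(fm, labels, ClassifierSpec("svm"),
                                positive_class="pos", k=10, n_select=20,
                                seed=1)
    assert np.all(cv.probabilities[cv.y == 1] > 0.5)
    assert np.all(cv.probabilities[cv.y == 0] < 0.5)


def test_every_sample_tested_exactly_once():
    fm, labels = gaussian_clouds(13, 7, 30, separation=1.0, seed=4)
    cv = crossval_probabilities(fm, labels, ClassifierSpec("sparse_logistic"),
                                positive_class="pos", k=10, seed=4)
    assert np.isfinite(cv.probabilities).all()
    assert np.bincount(cv.fold_ids, minlength=10).sum() == 20


def test_stowaway_feature_cannot_enter_selection():
    """Mutating held-out rows (e.g. a feature encoding the label only in
    test rows) never changes the per-fold selected feature sets."""
    rng = np.random.default_rng(8)
    fm, labels = gaussian_clouds(10, 10, 40, separation=0.5, seed=8)
    cv = crossval_probabilities(fm, labels, ClassifierSpec("sparse_logistic"),
                                positive_class="pos", k=5, n_select=10,
                                seed=3)
    for fold in range(5):
        test_rows = cv.fold_ids == fold
        X2 = fm.values.copy()
        X2[test_rows] = 1e9 * rng.normal(size=(test_rows.sum(), 40))
        fm2 = feature_matrix(X2)
        cv2 = crossval_probabilities(
            fm2, labels, ClassifierSpec("sparse_logistic"),
            positive_class="pos", k=5, n_select=10, seed=3)
        np.testing.assert_array_equal(cv.selected_features[fold],
                                      cv2.selected_features[fold])


def test_null_crossval_auc_centres_near_half():
    from gcimsvoc.performance import auc
    aucs = []
    for seed in range(12):
        fm, labels = gaussian_clouds(13, 7, 400, separation=0.0, seed=seed)
        cv = crossval_probabilities(fm, labels, ClassifierSpec("svm"),
                                    positive_class="pos", k=10,
                                    n_select=100, seed=seed)
        aucs.append(auc(cv.probabilities, cv.y.astype(bool)))
    assert 0.35 <= np.median(aucs) <= 0.65


def test_training_fold_collapsing_to_one_class_advises_smaller_k():
    fm, labels = gaussian_clouds(11, 1, 5, separation=1.0, seed=0)
    with pytest.raises(ValueError, match="smaller k"):
        crossval_probabilities(fm, labels, ClassifierSpec("sparse_logistic"),
                               positive_class="pos", k=12, n_select=3,
                               seed=0)


def test_crossval_deterministic_end_to_end():
    fm, labels = gaussian_clouds(9, 7, 25, separation=1.0, seed=6)
    runs = [crossval_probabilities(fm, labels, ClassifierSpec("neural_net"),
                                   positive_class="pos", k=4, n_select=10,
                                   seed=5) for _ in range(2)]
    np.testing.assert_array_equal(runs[0].probabilities,
                                  runs[1].probabilities)
    np.testing.assert_array_equal(runs[0].fold_ids, runs[1].fold_ids)
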