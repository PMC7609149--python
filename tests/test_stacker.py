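"""Stacked ensemble: folds, out-of-fold meta-features, meta-learner, RMSE."""

import warnings

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from threshseg import (
    EnsembleConfig,
    ThresholdStackingClassifier,
    build_meta_features,
    default_base_learners,
    default_meta_learner,
    ensemble_size_experiment,
    make_folds,
    predict_threshold,
    rmse,
    train_stacked,
)
from threshseg.io import load_model, save_model


class FirstFeatureClassifier(ClassifierMixin, BaseEstimator):
    """Test double: predicts whatever sits in feature column 0."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.asarray(X)[:, 0].astype(int)


def toy_problem(n=40, seed=0):
    """Two threshold classes linearly separable in two features."""
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.5, 150, 170)
    X = np.column_stack([y + rng.normal(0, 2, n), rng.normal(0, 1, n)])
    return X, y


class TestMakeFolds:
    def test_balanced_500_into_5(self):
        folds = make_folds(500, 5, seed=0)
        sizes = np.bincount(folds.assignments)
        assert list(sizes) == [100] * 5

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = sorted(np.bincount(make_folds(7, 5, seed=1).assignments))
        assert sizes == [1, 1, 1, 2, 2]

    def test_reproducible_under_seed(self):
        a = make_folds(50, 5, seed=3).assignments
        b = make_folds(50, 5, seed=3).assignments
        assert np.array_equal(a, b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, 5)


class TestBuildMetaFeatures:
    def test_two_fold_construction_matches_manual(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([150, 150, 170, 170])
        learner = ("tree", DecisionTreeClassifier(random_state=0))
        ds = build_meta_features(X, y, [learner], n_folds=2, seed=0)
        assert ds.meta_features.shape == (4, 1)
        # manual reconstruction with the same partition
        manual = np.empty(4)
        for fold in range(2):
            tr, te = ds.folds.train_test_indices(fold)
            m = DecisionTreeClassifier(random_state=0).fit(X[tr], y[tr])
            manual[te] = m.predict(X[te])
        assert np.array_equal(ds.meta_features.ravel(), manual)

    def test_constant_dummy_learner_fills_column(self):
        X, y = toy_problem()
        dummy = DummyClassifier(strategy="constant", constant=170)
        # the dummy needs 170 present in every training fold; it is, by design
        ds = build_meta_features(X, y, [("dummy", dummy)], n_folds=5, seed=0)
        assert np.all(ds.meta_features == 170)

    def test_out_of_fold_purity_bookkeeping(self):
        X, y = toy_problem(n=53, seed=2)
        learners = [("a", DecisionTreeClassifier(random_state=0)),
                    ("b", DummyClassifier(strategy="most_frequent"))]
        ds = build_meta_features(X, y, learners, n_folds=5, seed=1)
        for i in range(len(y)):
            for j in range(len(learners)):
                producer = ds.producer_fold[i, j]
                assert i not in ds.fold_train_indices[producer]


class TestThresholdStackingClassifier:
    def test_default_configuration_contract(self):
        model = ThresholdStackingClassifier()
        learners = model._resolved_learners()
        names = [n for n, _ in learners]
        assert names == ["random_forest", "extra_trees", "bagging", "adaboost", "svc"]
        types = [RandomForestClassifier, ExtraTreesClassifier, BaggingClassifier,
                 AdaBoostClassifier, SVC]
        assert all(isinstance(est, t) for (_, est), t in zip(learners, types))
        assert isinstance(default_meta_learner(), LogisticRegression)
        assert model.n_folds == 5

    def test_printed_hyperparameters(self):
        learners = dict(default_base_learners())
        rf = learners["random_forest"]
        assert rf.n_estimators == 150 and rf.max_depth == 200 and rf.oob_score
        svc = learners["svc"]
        assert svc.kernel == "sigmoid" and svc.gamma == 0.1
        assert svc.class_weight == "balanced" and svc.degree == 2
        et = learners["extra_trees"]
        assert et.n_estimators == 100 and et.bootstrap and et.max_features == "sqrt"
        bag = learners["bagging"]
        assert bag.n_estimators == 100 and bag.max_features == 0.5
        ada = learners["adaboost"]
        assert ada.n_estimators == 50 and ada.learning_rate == 0.1

    def test_perfect_base_learners_give_zero_meta_rmse(self):
        X, y = toy_problem(n=60, seed=1)
        X[:, 0] = y  # feature 0 carries the label exactly
        model = ThresholdStackingClassifier(
            base_learners=[("o1", FirstFeatureClassifier()), ("o2", FirstFeatureClassifier())],
            random_state=0,
        ).fit(X, y)
        assert np.all(model.meta_features_ == y[:, None])
        assert rmse(y, model.meta_model_.predict(model.meta_features_)) == 0.0
        # all base learners agree on a class -> meta predicts that class
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # inputs exceed the normalized range
            pred = model.predict(np.column_stack([np.full(3, 170.0), np.zeros(3)]))
        assert np.all(pred == 170)

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2))
        y = np.full(10, 160)
        with pytest.raises(ValueError):
            ThresholdStackingClassifier().fit(X, y)

    def test_learned_recovery_and_determinism(self):
        X, y = toy_problem(n=80, seed=3)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        m1 = ThresholdStackingClassifier(
            base_learners=default_base_learners(0)[:2], random_state=0
        ).fit(X, y)
        m2 = ThresholdStackingClassifier(
            base_learners=default_base_learners(0)[:2], random_state=0
        ).fit(X, y)
        p1, p2 = m1.predict(X), m2.predict(X)
        assert np.array_equal(p1, p2)
        assert rmse(y, p1) < 20.0  # well under the inter-class gap
        assert set(p1) <= set(y)

    def test_fold_clone_averaging_vs_refit_aggregation(self):
        X, y = toy_problem(n=60, seed=4)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        kw = dict(base_learners=[("tree", DecisionTreeClassifier(random_state=0))], random_state=0)
        avg = ThresholdStackingClassifier(aggregation="average", **kw).fit(X, y)
        refit = ThresholdStackingClassifier(aggregation="refit", **kw).fit(X, y)
        assert avg.predict_meta_features(X).shape == (60, 1)
        assert refit.predict_meta_features(X).shape == (60, 1)
        # refit aggregation must use the full-data model's predictions
        full = refit.base_full_models_["tree"].predict(X)
        assert np.array_equal(refit.predict_meta_features(X).ravel(), full.astype(float))

    def test_serialization_roundtrip_bit_identical(self, tmp_path):
        X, y = toy_problem(n=50, seed=5)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        model = train_stacked(X, y, EnsembleConfig(n_base_learners=2, seed=0))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        assert np.array_equal(model.predict(X), reloaded.predict(X))
        assert predict_threshold(reloaded, X[0]) == int(model.predict(X[:1])[0])

    def test_sklearn_get_set_params(self):
        model = ThresholdStackingClassifier(n_folds=3)
        assert model.get_params()["n_folds"] == 3
        model.set_params(aggregation="refit")
        assert model.aggregation == "refit"


class TestRmse:
    def test_hand_computed_values(self):
        assert rmse([170, 180], [172, 176]) == pytest.approx(3.1623, abs=1e-4)
        assert rmse([0], [10]) == 10.0
        assert rmse([5, 6], [5, 6]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            rmse([], [])


class TestEnsembleSizeExperiment:
    def test_rank_order_prefix(self):
        names = [n for n, _ in default_base_learners()]
        assert names[:2] == ["random_forest", "extra_trees"]

    def test_table_shape_and_columns(self):
        X, y = toy_problem(n=60, seed=6)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        table = ensemble_size_experiment(X[:48], y[:48], X[48:], y[48:], sizes=[1, 2], seed=0)
        assert list(table["size"]) == [1, 2]
        assert {"rmse", "fit_seconds", "predict_seconds"} <= set(table.columns)
        assert (table["rmse"] >= 0).all()

    def test_invalid_sizes_rejected(self):
        X, y = toy_problem()
        with pytest.raises(ValueError):
            ensemble_size_experiment(X, y, X, y, sizes=[0])
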