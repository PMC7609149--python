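"""Two-level stacked ensemble for optimal-threshold prediction.

The threshold search of the labeling stage turns segmentation into a
classification problem over discrete gray-level classes. A single
classifier trained on histogram features is serviceable but noisy; stacked
generalization improves it: five diverse base classifiers — random forest,
extremely randomized trees, bootstrap-aggregated trees, AdaBoost, and a
support-vector classifier, in that rank order — each produce out-of-fold
threshold predictions under 5-fold cross-validation, and those predictions
(one column per learner) become the inputs of a second-level softmax
(multinomial logistic) regression. Out-of-fold purity is what prevents the
meta-learner from overfitting to base-learner training error: no sample's
meta-feature was produced by a model that saw that sample.

At inference each base learner's five fold-trained clones predict and their
gray-level outputs are averaged into that learner's meta-feature
(``aggregation='refit'`` substitutes a single full-data refit); the
meta-learner's predicted class maps back to its gray level, ties broken
toward the larger threshold for consistency with the labeling rule.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "default_base_learners",
    "default_meta_learner",
    "EnsembleConfig",
    "FoldPartition",
    "MetaDataset",
    "ThresholdStackingClassifier",
    "make_folds",
    "build_meta_features",
    "train_stacked",
    "predict_threshold",
    "rmse",
    "ensemble_size_experiment",
]

_TIE_TOL = 1e-12


def default_base_learners(random_state: int | None = None) -> list[tuple[str, BaseEstimator]]:
    """The five default base classifiers, ordered by standalone accuracy
    (best first), each with its fixed published-style hyperparameters.

    Seeds: four learners carry fixed seeds as part of their settings; the
    random forest draws its seed from ``random_state`` (default 0) so the
    whole ensemble is reproducible from one knob.
    """
    rf_seed = 0 if random_state is None else int(random_state)
    return [
        (
            "random_forest",
            RandomForestClassifier(
                n_estimators=150, max_depth=200, max_features="sqrt",
                oob_score=True, random_state=rf_seed,
            ),
        ),
        (
            "extra_trees",
            ExtraTreesClassifier(
                n_estimators=100, class_weight="balanced", bootstrap=True,
                max_features="sqrt", oob_score=True, random_state=30,
            ),
        ),
        (
            "bagging",
            BaggingClassifier(n_estimators=100, max_features=0.5, oob_score=True, random_state=50),
        ),
        (
            "adaboost",
            AdaBoostClassifier(n_estimators=50, learning_rate=0.1, random_state=30),
        ),
        (
            "svc",
            SVC(
                kernel="sigmoid", gamma=0.1, degree=2, class_weight="balanced",
                max_iter=-1, random_state=5,
            ),
        ),
    ]


def default_meta_learner() -> LogisticRegression:
    """Softmax regression: multinomial logistic over the threshold classes."""
    return LogisticRegression(max_iter=5000)


@dataclass
class EnsembleConfig:
    """Declarative ensemble settings (the CLI/YAML-facing configuration)."""

    n_base_learners: int = 5
    n_folds: int = 5
    aggregation: str = "average"  # or "refit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 1 <= self.n_base_learners <= 5:
            raise ValueError("n_base_learners must be in 1..5")
        if self.aggregation not in ("average", "refit"):
            raise ValueError("aggregation must be 'average' or 'refit'")

    def build(self) -> "ThresholdStackingClassifier":
        return ThresholdStackingClassifier(
            base_learners=default_base_learners(self.seed)[: self.n_base_learners],
            n_folds=self.n_folds,
            aggregation=self.aggregation,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class FoldPartition:
    """Per-sample fold assignment in {0..k-1}; fold sizes differ by <= 1."""

    assignments: np.ndarray

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def make_folds(n: int, k: int = 5, seed: int | None = None) -> FoldPartition:
    """Random balanced k-fold partition, reproducible under ``seed``."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    assignments = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)))):
        assignments[test_idx] = fold
    return FoldPartition(assignments=assignments)


@dataclass
class MetaDataset:
    """Out-of-fold base-learner predictions and provenance bookkeeping.

    ``producer_fold[i, j]`` records which fold model of learner *j* produced
    sample *i*'s meta-feature; paired with ``fold_train_indices`` it lets a
    test assert out-of-fold purity directly.
    """

    meta_features: np.ndarray  # (n_samples, n_learners) predicted thresholds
    labels: np.ndarray
    folds: FoldPartition
    learner_names: list[str] = field(default_factory=list)
    producer_fold: np.ndarray | None = None
    fold_train_indices: dict[int, np.ndarray] = field(default_factory=dict)


def build_meta_features(
    X: np.ndarray,
    y: np.ndarray,
    base_learners: list[tuple[str, BaseEstimator]],
    n_folds: int = 5,
    seed: int | None = None,
    return_models: bool = False,
):
    """Construct the out-of-fold meta-feature matrix (one column per base
    learner). Optionally also return the per-fold fitted clones."""
    X, y = check_X_y(X, y)
    folds = make_folds(len(y), n_folds, seed)
    n, L = len(y), len(base_learners)
    meta = np.empty((n, L), dtype=np.float64)
    producer = np.empty((n, L), dtype=int)
    fold_models: dict[str, list[BaseEstimator]] = {name: [] for name, _ in base_learners}
    fold_train: dict[int, np.ndarray] = {}
    for fold in range(n_folds):
        train_idx, test_idx = folds.train_test_indices(fold)
        fold_train[fold] = train_idx
        for j, (name, est) in enumerate(base_learners):
            model = clone(est).fit(X[train_idx], y[train_idx])
            meta[test_idx, j] = model.predict(X[test_idx])
            producer[test_idx, j] = fold
            fold_models[name].append(model)
    ds = MetaDataset(
        meta_features=meta,
        labels=y,
        folds=folds,
        learner_names=[name for name, _ in base_learners],
        producer_fold=producer,
        fold_train_indices=fold_train,
    )
    if return_models:
        return ds, fold_models
    return ds


class ThresholdStackingClassifier(ClassifierMixin, BaseEstimator):
    """Stacked ensemble predicting per-image binarization thresholds.

    Parameters
    ----------
    base_learners : list of (name, estimator), optional
        First-level classifiers; defaults to the five-learner set of
        :func:`default_base_learners` in rank order.
    meta_learner : classifier, optional
        Second-level model; defaults to softmax regression.
    n_folds : int
        Cross-validation folds for out-of-fold meta-feature construction.
    aggregation : {'average', 'refit'}
        How a base learner's inference-time meta-feature is formed: average
        of its fold clones' predictions, or a single full-data refit.
    random_state : int, optional
        Seeds the fold shuffle and the random forest.

    Attributes
    ----------
    classes_ : ndarray
        Sorted distinct threshold labels (gray levels).
    meta_features_ : ndarray of shape (n_samples, n_learners)
        Out-of-fold training meta-features.
    base_fold_models_ : dict name -> list of k fitted clones.
    base_full_models_ : dict name -> full-data refit.
    meta_model_ : fitted second-level model.
    fold_partition_ : FoldPartition used during fit.
    oof_provenance_ : MetaDataset with purity bookkeeping.
    """

    def __init__(
        self,
        base_learners: list[tuple[str, BaseEstimator]] | None = None,
        meta_learner: BaseEstimator | None = None,
        n_folds: int = 5,
        aggregation: str = "average",
        random_state: int | None = None,
    ):
        self.base_learners = base_learners
        self.meta_learner = meta_learner
        self.n_folds = n_folds
        self.aggregation = aggregation
        self.random_state = random_state

    def _resolved_learners(self) -> list[tuple[str, BaseEstimator]]:
        if self.base_learners is None:
            return default_base_learners(self.random_state)
        return list(self.base_learners)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThresholdStackingClassifier":
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 distinct threshold classes to train")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.aggregation not in ("average", "refit"):
            raise ValueError("aggregation must be 'average' or 'refit'")
        learners = self._resolved_learners()
        if not learners:
            raise ValueError("need at least one base learner")

        ds, fold_models = build_meta_features(
            X, y, learners, n_folds=self.n_folds, seed=self.random_state, return_models=True
        )
        self.oof_provenance_ = ds
        self.meta_features_ = ds.meta_features
        self.fold_partition_ = ds.folds
        self.base_fold_models_ = fold_models
        self.base_full_models_ = {
            name: clone(est).fit(X, y) for name, est in learners
        }
        self.learner_names_ = [name for name, _ in learners]
        meta = self.meta_learner if self.meta_learner is not None else default_meta_learner()
        self.meta_model_ = clone(meta).fit(ds.meta_features, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _meta_inputs(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for name in self.learner_names_:
            if self.aggregation == "refit":
                cols.append(self.base_full_models_[name].predict(X).astype(np.float64))
            else:
                preds = np.stack(
                    [m.predict(X).astype(np.float64) for m in self.base_fold_models_[name]]
                )
                cols.append(preds.mean(axis=0))
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "meta_model_")
        X = check_array(X)
        if np.any((X < -0.1) | (X > 1.1)):
            import warnings

            warnings.warn(
                "input features fall outside [-0.1, 1.1]; did you forget "
                "min-max normalization with the training-set parameters?",
                stacklevel=2,
            )
        proba = self.meta_model_.predict_proba(self._meta_inputs(X))
        classes = np.asarray(self.meta_model_.classes_)
        out = np.empty(len(proba), dtype=int)
        for i, p in enumerate(proba):
            # argmax with ties broken toward the larger threshold class
            out[i] = classes[p >= p.max() - _TIE_TOL].max()
        return out

    def predict_meta_features(self, X: np.ndarray) -> np.ndarray:
        """Inference-time meta-feature matrix (one column per learner)."""
        check_is_fitted(self, "meta_model_")
        return self._meta_inputs(check_array(X))


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_stacked(
    X: np.ndarray,
    y: np.ndarray,
    config: EnsembleConfig | None = None,
) -> ThresholdStackingClassifier:
    """Fit the stacked model described by ``config`` (defaults: 5 learners,
    5 folds, averaging aggregation, seed 0)."""
    config = config if config is not None else EnsembleConfig()
    return config.build().fit(X, y)


def predict_threshold(model: ThresholdStackingClassifier, fv: np.ndarray) -> int:
    """Predict the threshold for one normalized feature vector."""
    return int(model.predict(np.asarray(fv, dtype=np.float64)[None, :])[0])


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error on gray-level values."""
    y, yhat = np.asarray(y, dtype=np.float64), np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def ensemble_size_experiment(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    sizes: list[int],
    n_folds: int = 5,
    aggregation: str = "average",
    seed: int | None = None,
) -> pd.DataFrame:
    """Accuracy/runtime sensitivity to the number of stacked base learners.

    Learners are added in rank order (size 2 = random forest + extra trees,
    and so on). Returns one row per size: test RMSE, fit and predict time.
    """
    available = default_base_learners(seed)
    if any(s < 1 or s > len(available) for s in sizes):
        raise ValueError(f"sizes must be within 1..{len(available)}")
    rows = []
    for size in sizes:
        model = ThresholdStackingClassifier(
            base_learners=available[:size],
            n_folds=n_folds,
            aggregation=aggregation,
            random_state=seed,
        )
        t0 = time.perf_counter()
        model.fit(X_train, y_train)
        t_fit = time.perf_counter() - t0
        t0 = time.perf_counter()
        yhat = model.predict(X_test)
        t_pred = time.perf_counter() - t0
        rows.append(
            {
                "size": size,
                "rmse": rmse(y_test, yhat),
                "fit_seconds": t_fit,
                "predict_seconds": t_pred,
            }
        )
    return pd.DataFrame(rows)
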