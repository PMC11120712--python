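"""Uniform train/predict contract for the four learners, plus evaluation.

The four genomic-prediction models — gradient-boosted trees (xgboost),
support vector machine (RBF kernel, C=1), k-nearest neighbours with
Euclidean distance, and random forest — are delegated to xgboost and
scikit-learn behind a single :class:`Learner` facade, so the selection
engine treats them interchangeably. Each learner runs either a
classification task (predicting the 3 trait levels directly) or a
regression task (predicting the continuous trait; real-valued predictions
are then mapped to levels with quartile thresholds learned from the
training values only, so regression runs are scored on the same
level-accuracy scale as classification runs).

Metrics: accuracy = (TP+TN)/(TP+TN+FP+FN), recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = 2·precision·recall/(precision+recall). In
the binary case these apply verbatim with the larger label as the
positive class; with three levels, precision/recall/F1 are macro-averaged
over one-vs-rest classes and accuracy is the trace fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

LEARNER_KINDS = ("gbt", "svm", "knn", "rf")
TASKS = ("classify", "regress")


@dataclass(frozen=True)
class LearnerSpec:
    """Configuration of one learner; hyperparameters beyond these are
    fixed at library defaults (recorded here: SVM kernel RBF with C=1)."""

    kind: str
    task: str = "classify"
    k_neighbors: int = 5
    n_trees: int = 100
    seed: int = 0
    svm_c: float = 1.0
    svm_kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.k_neighbors < 1 or self.n_trees < 1:
            raise ValueError("k_neighbors and n_trees must be positive")


class Learner:
    """Thin facade over a fitted estimator with label de/encoding."""

    def __init__(self, spec: LearnerSpec, estimator):
        self.spec = spec
        self._est = estimator
        self._classes: np.ndarray | None = None

    def fit(self, features: np.ndarray, target: np.ndarray) -> "Learner":
        X = np.asarray(features, dtype=float)
        y = np.asarray(target)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and target must align")
        if self.spec.task == "classify":
            self._classes, y_enc = np.unique(y, return_inverse=True)
            if self.spec.kind == "knn" and self.spec.k_neighbors >= X.shape[0]:
                raise ValueError("k_neighbors must be < n_train")
            self._est.fit(X, y_enc)
        else:
            self._est.fit(X, y.astype(float))
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        pred = self._est.predict(X)
        if self.spec.task == "classify":
            return self._classes[np.asarray(pred, dtype=int)]
        return np.asarray(pred, dtype=float)


def build_learner(spec: LearnerSpec) -> Learner:
    """Instantiate the estimator behind a spec; deterministic given its seed."""
    if spec.kind == "gbt":
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBClassifier if spec.task == "classify" else XGBRegressor
        est = cls(
            n_estimators=spec.n_trees,
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        )
    elif spec.kind == "svm":
        from sklearn.svm import SVC, SVR

        if spec.task == "classify":
            est = SVC(C=spec.svm_c, kernel=spec.svm_kernel, random_state=spec.seed)
        else:
            est = SVR(C=spec.svm_c, kernel=spec.svm_kernel)
    elif spec.kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

        cls = KNeighborsClassifier if spec.task == "classify" else KNeighborsRegressor
        est = cls(n_neighbors=spec.k_neighbors, metric="euclidean")
    elif spec.kind == "rf":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        cls = RandomForestClassifier if spec.task == "classify" else RandomForestRegressor
        est = cls(n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1)
    else:
        raise ValueError(f"unknown learner kind {spec.kind!r}")
    return Learner(spec, est)


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true levels, columns predictions."""

    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_binary_counts(
        cls, tp: int, fp: int, fn: int, tn: int, labels: Sequence = (0, 1)
    ) -> "ConfusionMatrix":
        """Build a 2x2 table from TP/FP/FN/TN with labels[1] as positive."""
        return cls(list(labels), np.array([[tn, fp], [fn, tp]]))

    def class_counts(self, index: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for the class at ``index``."""
        tp = int(self.counts[index, index])
        fp = int(self.counts[:, index].sum()) - tp
        fn = int(self.counts[index, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(true_levels, predicted_levels, labels=None) -> ConfusionMatrix:
    """Count table of true vs predicted labels."""
    t = np.asarray(true_levels)
    p = np.asarray(predicted_levels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted labels must be 1-D and aligned")
    if labels is None:
        labels = sorted(set(t.tolist()) | set(p.tolist()))
    else:
        labels = list(labels)
        unknown = (set(t.tolist()) | set(p.tolist())) - set(labels)
        if unknown:
            raise ValueError(f"unknown label(s) {sorted(unknown)}")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(labels, counts)


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalMetrics":
        return cls(d["accuracy"], d["precision"], d["recall"], d["f1"])


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def metrics_from_confusion(cm: ConfusionMatrix) -> EvalMetrics:
    """Accuracy/precision/recall/F1 from a confusion matrix.

    Binary tables use the larger label as the positive class; K > 2 tables
    macro-average precision, recall and F1 over one-vs-rest classes.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm.counts)) / cm.total
    k = len(cm.labels)
    if k == 2:
        pos = int(np.argmax(cm.labels))  # larger label is the positive class
        precision, recall, f1 = _prf(*cm.class_counts(pos)[:3])
    else:
        ps, rs, fs = zip(*(_prf(*cm.class_counts(i)[:3]) for i in range(k)))
        precision, recall, f1 = (
            float(np.mean(ps)),
            float(np.mean(rs)),
            float(np.mean(fs)),
        )
    return EvalMetrics(accuracy, float(precision), float(recall), float(f1))


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """How a learner is scored: resubstitution, hold-out, or k-fold CV."""

    kind: str = "resubstitution"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("resubstitution", "holdout", "cv"):
            raise ValueError(f"unknown protocol {self.kind!r}")
        if self.kind == "cv" and self.n_folds < 2:
            raise ValueError("cv needs at least 2 folds")


def _regression_thresholds(train_values: np.ndarray) -> tuple[float, float]:
    q25, q75 = np.quantile(train_values, [0.25, 0.75])
    return float(q25), float(q75)


def _bin_by_thresholds(values: np.ndarray, q25: float, q75: float) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return 1 + (v > q25).astype(int) + (v > q75).astype(int)


def _score_fold(
    spec: LearnerSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
) -> EvalMetrics:
    learner = build_learner(spec).fit(X_train, y_train)
    pred = learner.predict(X_eval)
    if spec.task == "regress":
        q25, q75 = _regression_thresholds(np.asarray(y_train, dtype=float))
        true_lv = _bin_by_thresholds(y_eval, q25, q75)
        pred_lv = _bin_by_thresholds(pred, q25, q75)
        cm = confusion(true_lv, pred_lv, labels=[1, 2, 3])
    else:
        cm = confusion(y_eval, pred)
    return metrics_from_confusion(cm)


def evaluate(
    spec: LearnerSpec,
    features: np.ndarray,
    target: np.ndarray,
    protocol: Protocol = Protocol(),
    features_test: np.ndarray | None = None,
    target_test: np.ndarray | None = None,
) -> EvalMetrics:
    """Train and score one learner under a protocol.

    ``target`` is the level vector for the classify task and the
    continuous trait for the regress task (scored after quartile binning
    with thresholds from the training values only). ``cv`` refits the
    learner per fold and returns the mean of each metric over folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target)
    if protocol.kind == "resubstitution":
        return _score_fold(spec, X, y, X, y)
    if protocol.kind == "holdout":
        if features_test is None or target_test is None:
            raise ValueError("holdout protocol requires a test set")
        return _score_fold(
            spec, X, y, np.asarray(features_test, dtype=float), np.asarray(target_test)
        )
    # k-fold CV, deterministic given the protocol seed
    from sklearn.model_selection import KFold, StratifiedKFold

    if spec.task == "classify":
        splitter = StratifiedKFold(
            n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
        )
        folds = splitter.split(X, y)
    else:
        splitter = KFold(
            n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
        )
        folds = splitter.split(X)
    per_fold = [
        _score_fold(spec, X[tr], y[tr], X[te], y[te]) for tr, te in folds
    ]
    return EvalMetrics(
        float(np.mean([m.accuracy for m in per_fold])),
        float(np.mean([m.precision for m in per_fold])),
        float(np.mean([m.recall for m in per_fold])),
        float(np.mean([m.f1 for m in per_fold])),
    )
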