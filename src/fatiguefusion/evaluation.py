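"""Evaluation harness: confusion matrices, accuracy, k-fold CV, baselines.

The fused classifier is evaluated with the fatigued class as positive.
``kfold_cv`` performs seeded stratified k-fold cross-validation (default
k=3), refitting the domain scorers and fusion weights on each training
split so no fold's test data leaks into its own training. The baseline
comparison trains five standard classifiers (kNN, a randomized decision
tree, random forest, RBF-kernel SVM, and a one-hidden-layer perceptron) on
the flat 20-feature matrix under the same split, as a reference harness for
the fusion method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidParameterError, ValidationError
from .fusion import ALERT, FATIGUED, FatigueFusionModel, SubjectRecord, DOMAINS

__all__ = [
    "ConfusionMatrix",
    "FoldReport",
    "confusion_matrix",
    "accuracy",
    "kfold_cv",
    "baseline_comparison",
    "BASELINE_CLASSIFIERS",
    "records_to_frame",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with fatigued as the positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.TP, self.FN, self.FP, self.TN)


@dataclass(frozen=True)
class FoldReport:
    """Per-fold confusion matrices and accuracies plus their arithmetic mean."""

    matrices: tuple[ConfusionMatrix, ...]
    accuracies: tuple[float, ...]  # percent
    average_accuracy: float  # percent

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": i + 1,
                "TP": m.TP,
                "FN": m.FN,
                "FP": m.FP,
                "TN": m.TN,
                "accuracy_pct": round(a, 2),
            }
            for i, (m, a) in enumerate(zip(self.matrices, self.accuracies))
        ]
        return pd.DataFrame(rows)


def confusion_matrix(
    predicted: Sequence[int], actual: Sequence[int]
) -> ConfusionMatrix:
    """Standard 2x2 counts; fatigued (1) is the positive class."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape or p.size == 0:
        raise InvalidParameterError("predicted and actual must be equal-length, non-empty")
    return ConfusionMatrix(
        TP=int(np.sum((p == FATIGUED) & (a == FATIGUED))),
        FN=int(np.sum((p == ALERT) & (a == FATIGUED))),
        FP=int(np.sum((p == FATIGUED) & (a == ALERT))),
        TN=int(np.sum((p == ALERT) & (a == ALERT))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """100 * (TP + TN) / total, in percent."""
    if cm.total == 0:
        raise InvalidParameterError("empty confusion matrix")
    return 100.0 * (cm.TP + cm.TN) / cm.total


def kfold_cv(
    records: Sequence[SubjectRecord],
    k: int = 3,
    seed: int = 0,
    model_params: dict | None = None,
) -> FoldReport:
    """Stratified k-fold cross-validation of the full fusion pipeline.

    Folds come from a seeded stratified shuffle; within each fold the domain
    scorers and the fusion weights are fitted on the training split only and
    evaluated on the held-out split. The report carries per-fold confusion
    matrices, per-fold accuracies (percent) and their arithmetic mean.
    """
    labelled = [r for r in records if r.label is not None]
    y = np.array([r.label for r in labelled])
    if min(np.sum(y == ALERT), np.sum(y == FATIGUED)) < k:
        raise InvalidParameterError(f"need >= {k} records per class for {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    matrices: list[ConfusionMatrix] = []
    accs: list[float] = []
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        train = [labelled[i] for i in train_idx]
        test = [labelled[i] for i in test_idx]
        if len({r.label for r in train}) < 2:
            raise ValidationError("a class is absent from a fold's training set")
        model = FatigueFusionModel(**(model_params or {})).fit(train)
        cm = confusion_matrix(model.predict(test), [r.label for r in test])
        matrices.append(cm)
        accs.append(accuracy(cm))
    return FoldReport(
        matrices=tuple(matrices),
        accuracies=tuple(accs),
        average_accuracy=float(np.mean(accs)),
    )


def _baseline_factories(seed: int) -> dict:
    return {
        "kNN": lambda: make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=5)
        ),
        "random_tree": lambda: DecisionTreeClassifier(
            max_features="sqrt", random_state=seed
        ),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "SVM": lambda: make_pipeline(StandardScaler(), SVC(kernel="rbf")),
        "MLP": lambda: make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=2000, random_state=seed
            ),
        ),
    }


BASELINE_CLASSIFIERS = ("kNN", "random_tree", "random_forest", "SVM", "MLP")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flat feature table: subject_id, label, then all 20 named features."""
    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id, "label": r.label}
        for domain in DOMAINS:
            vec = getattr(r, domain)
            names = type(vec).__dataclass_fields__
            arr = vec.as_array()
            for name, value in zip(names, arr):
                row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_comparison(
    feature_matrix: np.ndarray,
    labels: Sequence[int],
    test_size: float | int = 0.333,
    seed: int = 0,
    classifiers: Sequence[str] = BASELINE_CLASSIFIERS,
) -> pd.DataFrame:
    """Train/evaluate the named baselines under one stratified split.

    Hyperparameters are fixed and recorded in the result: kNN k=5, SVM with
    an RBF kernel, random forest with 100 trees, MLP with one hidden layer
    of 16 units, randomized decision tree with default depth. Returns a
    table of (classifier, accuracy %, correct, incorrect). NaN feature
    columns are dropped before fitting.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    if min(np.sum(y == ALERT), np.sum(y == FATIGUED)) < 2:
        raise InvalidParameterError("need >= 2 subjects per class")
    keep = [j for j in range(X.shape[1]) if not np.isnan(X[:, j]).any()]
    X = X[:, keep]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    factories = _baseline_factories(seed)
    params = {
        "kNN": "k=5",
        "random_tree": "random-split tree, default depth",
        "random_forest": "100 trees",
        "SVM": "RBF kernel",
        "MLP": "1 hidden layer x 16",
    }
    rows = []
    for name in classifiers:
        if name not in factories:
            raise InvalidParameterError(f"unknown classifier {name!r}")
        clf = factories[name]()
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        correct = int(np.sum(pred == y_te))
        rows.append(
            {
                "classifier": name,
                "hyperparameters": params[name],
                "accuracy_pct": round(100.0 * correct / len(y_te), 2),
                "correct": correct,
                "incorrect": len(y_te) - correct,
            }
        )
    return pd.DataFrame(rows)
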