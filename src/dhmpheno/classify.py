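"""Balanced, cross-validated phenotype classification and mixture recovery.

Four fixed classifier configurations are supported:

* ``random_forest`` — 100 trees, no depth bound
* ``svm`` — RBF kernel, C = 1, one-against-one
* ``knn`` — k = 5, Euclidean distance
* ``neural_net`` — one hidden layer of 100 units, cross-entropy loss,
  Adam optimiser, batch size 256

Datasets are balanced by seeded random undersampling to the minority
class, then evaluated with stratified 5-fold cross-validation; accuracy is
the plain fraction correct on each held-out fold.  Features are z-scored
inside each training fold for the margin/distance-based methods (svm, knn,
neural_net); trees consume raw features.

Mixture (spike-in) quantification trains on pure populations only and
reports the fraction of mixed-population cells predicted per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "METHODS",
    "ClassifierSpec",
    "ClassifierReport",
    "make_estimator",
    "balance_classes",
    "cross_validate",
    "train_classifier",
    "quantify_mixture",
]

METHODS = ("random_forest", "svm", "knn", "neural_net")


@dataclass(frozen=True)
class ClassifierSpec:
    method: str = "random_forest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")


def make_estimator(spec: ClassifierSpec):
    """Build the fixed estimator for a method (no hyperparameter search)."""
    if spec.method == "random_forest":
        return RandomForestClassifier(n_estimators=100, max_depth=None,
                                      random_state=spec.seed)
    if spec.method == "svm":
        est = SVC(C=1.0, kernel="rbf", decision_function_shape="ovo",
                  random_state=spec.seed)
    elif spec.method == "knn":
        # ties in the 5-neighbour vote resolve to the lowest class index
        est = KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    else:
        est = MLPClassifier(hidden_layer_sizes=(100,), solver="adam",
                            batch_size=256, max_iter=300,
                            n_iter_no_change=10, tol=1e-4,
                            random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass
class ClassifierReport:
    method: str
    seed: int
    fold_accuracies: np.ndarray
    per_cell_predictions: np.ndarray  # held-out prediction per evaluated cell
    per_cell_index: np.ndarray        # row index of each evaluated cell
    confusion: np.ndarray
    classes: list[str]
    class_balance_applied: bool = False

    @property
    def median(self) -> float:
        return float(np.median(self.fold_accuracies))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.fold_accuracies, [25, 75])
        return float(q1), float(q3)

    def to_dict(self) -> dict:
        q1, q3 = self.quartiles
        return {
            "method": self.method,
            "seed": self.seed,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "median": self.median,
            "quartiles": [q1, q3],
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "class_balance_applied": self.class_balance_applied,
        }


def balance_classes(X: np.ndarray, y: np.ndarray, seed: int = 0,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded random undersampling of every class to the minority size.

    Returns (X_balanced, y_balanced, original_indices); indices preserve
    provenance and ascend within the output.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to balance")
    if counts.min() == 0:  # unreachable via np.unique; guards empty input
        raise ValueError("empty class encountered")
    n_min = counts.min()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    order = np.sort(np.concatenate(keep))
    return X[order], y[order], order


def cross_validate(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                   n_folds: int = 5, balanced: bool = True,
                   ) -> ClassifierReport:
    """Stratified, seeded k-fold evaluation with per-fold accuracies."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} cells; "
            f"need at least {n_folds} per class for {n_folds}-fold CV")
    if counts.min() < 10:
        raise ValueError("need at least 10 cells per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    accs = np.empty(n_folds)
    preds = np.empty(y.shape, dtype=y.dtype)
    idx_all = np.arange(y.size)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        est = clone(make_estimator(spec))
        est.fit(X[tr], y[tr])
        p = est.predict(X[te])
        preds[te] = p
        accs[k] = float(np.mean(p == y[te]))
    conf = confusion_matrix(y, preds, labels=classes)
    return ClassifierReport(method=spec.method, seed=spec.seed,
                            fold_accuracies=accs, per_cell_predictions=preds,
                            per_cell_index=idx_all, confusion=conf,
                            classes=[str(c) for c in classes],
                            class_balance_applied=balanced)


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Fit the fixed estimator on pure/training data; returns the estimator."""
    est = make_estimator(spec)
    est.fit(np.asarray(X, dtype=float), np.asarray(y))
    return est


def quantify_mixture(trained_classifier, X_mixed: np.ndarray) -> dict[str, float]:
    """Per-class predicted fractions in a mixed population; fractions sum
    to 1 over the classifier's classes."""
    X_mixed = np.asarray(X_mixed, dtype=float)
    if X_mixed.shape[0] == 0:
        raise ValueError("empty mixture: no cells to classify")
    preds = trained_classifier.predict(X_mixed)
    classes = getattr(trained_classifier, "classes_", None)
    if classes is None:  # sklearn Pipeline
        classes = trained_classifier[-1].classes_
    n = preds.shape[0]
    return {str(c): float(np.sum(preds == c)) / n for c in classes}
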