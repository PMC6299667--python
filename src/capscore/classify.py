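"""Classifiers for per-second CAP scoring: DA, k-NN and one-against-all SVM.

Discriminant analysis is fitted by closed-form Gaussian discriminants
(decision surfaces equivalent to least-squares-trained linear/quadratic
discriminant functions, and far better conditioned).  k-NN uses the
Euclidean metric with majority vote, ties broken toward the nearest
neighbor's class.  The SVM is a soft-margin machine with the Gaussian
kernel exp(-gamma ||xi - xj||^2), combined one-against-all for
multi-class problems: the class with the largest decision value wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

#: the k values evaluated for k-NN
KNN_GRID = (3, 5, 7, 9, 15, 25)
#: full SVM grids: C = 2^-5, 2^-3, ..., 2^15 and gamma = 2^-15, 2^-13, ..., 2^5
C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 6, 2))

SVM_TOL = 1e-3  # fixed solver tolerance: keeps fits deterministic


@dataclass
class TrainedClassifier:
    kind: str                      # LDA | QDA | KNN | SVM_OVA
    model: object
    classes: np.ndarray
    feature_names: list | None = None
    params: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "KNN":
            return self._predict_knn(X)
        return self.model.predict(X)

    def _predict_knn(self, X: np.ndarray) -> np.ndarray:
        nn, y_train = self.model
        dist, idx = nn.kneighbors(X)
        out = np.empty(len(X), dtype=y_train.dtype)
        for i in range(len(X)):
            votes = y_train[idx[i]]
            classes, counts = np.unique(votes, return_counts=True)
            winners = classes[counts == counts.max()]
            if len(winners) == 1:
                out[i] = winners[0]
            else:  # tie: the nearest neighbor belonging to a tied class decides
                for lab in votes:  # idx is sorted by distance
                    if lab in winners:
                        out[i] = lab
                        break
        return out


@dataclass
class GridSearchResult:
    grid: list          # (C, gamma, mean WAC) triples
    best_C: float
    best_gamma: float
    best_wac: float


def _check_training(X: np.ndarray, y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")


def train_da(features, labels, form: str = "linear",
             feature_names=None) -> TrainedClassifier:
    """Linear or quadratic discriminant analysis.

    Predicts the class whose discriminant function g_k(x) is largest.
    A singular within-class scatter is handled by the solver's shrinkage
    (LDA) / a small regularization ridge (QDA).
    """
    X = np.asarray(features, dtype=float)
    y = _labels_array(labels)
    _check_training(X, y)
    if form == "linear":
        model = LinearDiscriminantAnalysis(solver="svd")
    elif form == "quadratic":
        model = QuadraticDiscriminantAnalysis(reg_param=1e-6)
    else:
        raise ValueError(f"unknown DA form {form!r}")
    model.fit(X, y)
    return TrainedClassifier(kind="LDA" if form == "linear" else "QDA",
                             model=model, classes=model.classes_,
                             feature_names=feature_names, params={"form": form})


def train_knn(features, labels, k: int = 25, feature_names=None) -> TrainedClassifier:
    """k-nearest-neighbors with Euclidean metric and nearest-tie-break voting."""
    X = np.asarray(features, dtype=float)
    y = _labels_array(labels)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the training size {len(X)}")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean")
    nn.fit(X)
    return TrainedClassifier(kind="KNN", model=(nn, y), classes=np.unique(y),
                             feature_names=feature_names, params={"k": k})


def train_svm_ova(features, labels, C: float = 0.5, gamma: float = 0.5,
                  feature_names=None) -> TrainedClassifier:
    """One-against-all soft-margin SVMs with the Gaussian kernel.

    For c classes, c binary machines are trained (class i against the
    rest); prediction takes the class with the largest decision value.
    For c = 2 a single binary machine suffices.
    """
    X = np.asarray(features, dtype=float)
    y = _labels_array(labels)
    _check_training(X, y)
    base = SVC(C=C, gamma=gamma, kernel="rbf", tol=SVM_TOL, cache_size=500)
    model = OneVsRestClassifier(base)
    model.fit(X, y)
    return TrainedClassifier(kind="SVM_OVA", model=model, classes=model.classes_,
                             feature_names=feature_names,
                             params={"C": C, "gamma": gamma})


def grid_search_svm(subject_features, subject_labels, C_grid=C_GRID,
                    gamma_grid=GAMMA_GRID) -> GridSearchResult:
    """Grid search of (C, gamma) by mean leave-one-subject-out weighted accuracy.

    ``subject_features``/``subject_labels`` are parallel per-subject lists;
    each grid point is scored by the mean WAC over folds that leave one
    subject out.  Ties are broken toward smaller C, then smaller gamma.
    """
    from capscore.evaluate import confusion, metrics

    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("grids must be non-empty")
    if len(subject_features) < 2:
        raise ValueError("grid search needs at least 2 subjects")
    X_list = [np.asarray(X, dtype=float) for X in subject_features]
    y_list = [_labels_array(y) for y in subject_labels]
    classes = np.unique(np.concatenate(y_list))

    results = []
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            wacs = []
            for hold in range(len(X_list)):
                X_tr = np.vstack([X for i, X in enumerate(X_list) if i != hold])
                y_tr = np.concatenate([y for i, y in enumerate(y_list) if i != hold])
                clf = train_svm_ova(X_tr, y_tr, C=C, gamma=gamma)
                pred = clf.predict(X_list[hold])
                cm = confusion(y_list[hold], pred, classes=classes)
                wacs.append(metrics(cm).wac)
            results.append((C, gamma, float(np.mean(wacs))))
    best_C, best_gamma, best_wac = max(results, key=lambda r: (r[2], -r[0], -r[1]))
    return GridSearchResult(grid=results, best_C=best_C, best_gamma=best_gamma,
                            best_wac=best_wac)


def _labels_array(labels) -> np.ndarray:
    from capscore.recording import LabelSeries

    if isinstance(labels, LabelSeries):
        return labels.labels
    return np.asarray(labels)
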