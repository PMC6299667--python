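"""Feature reduction: mRMR ranking and PCA projection.

mRMR ranks features greedily by mutual information with the class labels
minus the mean mutual information with the already-selected features (the
MID difference criterion).  Features are discretized into 3 quantile
levels before MI estimation.  PCA is the ordinary centered-covariance
eigendecomposition; inside cross-validation both are fitted on training
subjects only and merely applied to the test subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import mutual_info_score

from capscore.features import FeatureMatrix
from capscore.recording import LabelSeries

N_MRMR_BINS = 3


@dataclass
class FeatureRanking:
    ordered_names: list
    scores: np.ndarray  # relevance - redundancy at the step each feature was picked

    def top(self, n: int) -> list:
        return self.ordered_names[:n]


@dataclass
class ProjectionModel:
    mean_vector: np.ndarray
    components: np.ndarray          # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray  # non-increasing
    feature_names: list

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _discretize(x: np.ndarray, bins: int = N_MRMR_BINS) -> np.ndarray:
    """Quantile-bin a feature into ``bins`` levels (constant rows -> one level)."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mrmr_rank(matrix: FeatureMatrix, labels) -> FeatureRanking:
    """Greedy minimum-redundancy maximum-relevance ranking of all features."""
    y = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels)
    if matrix.n_seconds != len(y):
        raise ValueError("feature matrix and labels are not aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to rank features")

    names = matrix.names
    disc = {n: _discretize(matrix.row(n)) for n in names}
    relevance = {n: mutual_info_score(disc[n], y) for n in names}

    remaining = list(names)
    selected: list[str] = []
    scores: list[float] = []
    red_sum = {n: 0.0 for n in names}  # sum of MI(candidate, selected)
    while remaining:
        if not selected:
            crit = {n: relevance[n] for n in remaining}
        else:
            crit = {n: relevance[n] - red_sum[n] / len(selected) for n in remaining}
        best = max(remaining, key=lambda n: (crit[n], -names.index(n)))
        selected.append(best)
        scores.append(crit[best])
        remaining.remove(best)
        for n in remaining:
            red_sum[n] += mutual_info_score(disc[n], disc[best])
    return FeatureRanking(ordered_names=selected, scores=np.asarray(scores))


def pca_fit(matrix: FeatureMatrix, n_components: int) -> ProjectionModel:
    """Fit PCA on the (seconds x features) data of one or more subjects."""
    X = matrix.samples()
    max_rank = min(X.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds the data rank bound {max_rank}; clipped",
            stacklevel=2,
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    return ProjectionModel(
        mean_vector=model.mean_,
        components=model.components_,
        explained_variance=model.explained_variance_,
        feature_names=matrix.names,
    )


def pca_transform(model: ProjectionModel, matrix: FeatureMatrix) -> np.ndarray:
    """Project a feature matrix on the retained components: (seconds x n_components)."""
    if matrix.names != model.feature_names:
        raise ValueError("feature names do not match the fitted projection model")
    return (matrix.samples() - model.mean_vector) @ model.components.T
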