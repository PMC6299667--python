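"""Duration post-filtering, confusion accounting, SE/SP/AC/WAC metrics and
leave-one-subject-out orchestration.

Scored A-phases must last 2-60 s, so a run of exactly one predicted
A-second, or of more than 60 consecutive A-seconds, is relabeled as
background.  Metrics follow the per-class true/false positive/negative
decomposition of the confusion matrix (rows = predicted, columns = true):
SE_k = TP_k/(TP_k+FN_k), SP_k = TN_k/(TN_k+FP_k), AC = trace/total, and
the class-imbalance-robust weighted accuracy WAC = (1/K) sum_j n_jj/n_+j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from capscore.classify import GridSearchResult, train_da, train_knn, train_svm_ova, grid_search_svm
from capscore.conditioning import ConditioningConfig, condition
from capscore.features import FeatureMatrix, concat_feature_matrices
from capscore.recording import CLASS_NAMES, LabelSeries
from capscore.reduction import mrmr_rank, pca_fit, pca_transform


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_normalized(self) -> np.ndarray:
        """Columns scaled to percentages of each true class (NaN for empty)."""
        col = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / col

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("class name mismatch")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_names))


@dataclass
class MetricsReport:
    sensitivity: dict           # per class k: TP_k / (TP_k + FN_k)
    specificity: dict           # per class k: TN_k / (TN_k + FP_k)
    accuracy: float             # trace / total
    wac: float                  # mean per-true-class recall
    per_subject: dict = field(default_factory=dict)


def duration_filter(predicted: LabelSeries) -> LabelSeries:
    """Relabel A-runs of length 1 or longer than 60 s as background.

    Runs are defined on the A-vs-B collapse; a surviving run keeps its
    per-second subtype labels.  The operation is idempotent.
    """
    labels = predicted.labels.copy()
    is_a = labels > 0
    n = len(labels)
    t = 0
    while t < n:
        if is_a[t]:
            start = t
            while t < n and is_a[t]:
                t += 1
            run = t - start
            if run == 1 or run > 60:
                labels[start:t] = 0
        else:
            t += 1
    return LabelSeries(labels, predicted.subject_id)


def confusion(true, predicted, classes=None) -> ConfusionMatrix:
    """counts[i, j] = seconds predicted as class i whose true class is j."""
    y_true = true.labels if isinstance(true, LabelSeries) else np.asarray(true)
    y_pred = predicted.labels if isinstance(predicted, LabelSeries) else np.asarray(predicted)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted series have different lengths")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for i, ci in enumerate(classes):
        pred_i = y_pred == ci
        for j, cj in enumerate(classes):
            counts[i, j] = int(np.sum(pred_i & (y_true == cj)))
    names = [CLASS_NAMES[c] if 0 <= c < len(CLASS_NAMES) else str(c) for c in classes]
    return ConfusionMatrix(counts, names)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """SE/SP per class, overall accuracy and weighted accuracy.

    A true class with no instances has undefined sensitivity; it is
    reported as NaN and excluded from the WAC average, with a warning.
    """
    n = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    col = n.sum(axis=0)  # n_{+,k}: instances whose true class is k
    row = n.sum(axis=1)  # n_{k,+}: instances predicted as k
    se, sp = {}, {}
    recalls = []
    for k, name in enumerate(cm.class_names):
        tp = n[k, k]
        fp = row[k] - tp
        fn = col[k] - tp
        tn = total - tp - fp - fn
        if col[k] == 0:
            warnings.warn(f"true class {name} is empty; excluded from WAC", stacklevel=2)
            se[name] = float("nan")
        else:
            se[name] = tp / (tp + fn)
            recalls.append(se[name])
        sp[name] = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return MetricsReport(
        sensitivity=se,
        specificity=sp,
        accuracy=float(np.trace(n) / total),
        wac=float(np.mean(recalls)),
    )


# ---------------------------------------------------------------------------
# leave-one-subject-out orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One evaluation configuration for the cross-validated pipeline."""

    task: str = "binary"            # "binary" (A vs B) or "multiclass"
    classifier: str = "knn"         # knn | lda | qda | svm
    reduction: str = "mrmr"         # mrmr | pca | none
    n_features: int = 30            # features kept (mRMR) or components (PCA)
    k: int = 25                     # k-NN neighbors
    svm_C: float = 0.5
    svm_gamma: float = 0.5
    apply_duration_filter: bool = True
    precondition: bool = True       # run per-subject conditioning first


@dataclass
class LosoReport:
    """Cross-validation outcome: pooled and mean-per-fold views."""

    pooled: MetricsReport
    pooled_confusion: ConfusionMatrix
    fold_confusions: list
    fold_metrics: list
    fold_subjects: list
    mean_wac: float
    mean_accuracy: float


def _task_labels(series: LabelSeries, task: str) -> np.ndarray:
    if task == "binary":
        return series.binary()
    if task == "multiclass":
        return series.labels
    raise ValueError(f"unknown task {task!r}")


def leave_one_subject_out(features_by_subject, labels_by_subject,
                          config: PipelineConfig | None = None) -> LosoReport:
    """Evaluate one pipeline configuration with leave-one-subject-out CV.

    ``features_by_subject`` is a list of per-subject ``FeatureMatrix``
    (raw or already conditioned, see ``config.precondition``);
    ``labels_by_subject`` the parallel ground-truth ``LabelSeries``.
    Ranking/PCA and the classifier are fitted on the training subjects of
    each fold only; the held-out subject is transformed and predicted,
    duration-filtered, and scored.
    """
    config = config or PipelineConfig()
    m = len(features_by_subject)
    if m < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if len(labels_by_subject) != m:
        raise ValueError("features and labels cohorts differ in length")

    if config.precondition:
        cond_cfg = ConditioningConfig()
        features_by_subject = [condition(fm, cond_cfg) for fm in features_by_subject]

    classes = np.array([0, 1]) if config.task == "binary" else np.array([0, 1, 2, 3])
    fold_cms, fold_mets, fold_subjects = [], [], []
    for hold in range(m):
        train_idx = [i for i in range(m) if i != hold]
        test_fm = features_by_subject[hold]
        test_labels = labels_by_subject[hold]
        assert test_fm.subject_id not in {features_by_subject[i].subject_id for i in train_idx}

        train_fm = concat_feature_matrices([features_by_subject[i] for i in train_idx])
        y_train = np.concatenate(
            [_task_labels(labels_by_subject[i], config.task) for i in train_idx])
        y_test = _task_labels(test_labels, config.task)
        if not (y_test > 0).any():
            warnings.warn(f"subject {test_fm.subject_id} has no A-phases", stacklevel=2)

        if config.reduction == "mrmr":
            ranking = mrmr_rank(train_fm, y_train)
            keep = ranking.top(config.n_features)
            X_train = train_fm.samples(keep)
            X_test = test_fm.samples(keep)
        elif config.reduction == "pca":
            model = pca_fit(train_fm, config.n_features)
            X_train = pca_transform(model, train_fm)
            X_test = pca_transform(model, test_fm)
        elif config.reduction == "none":
            X_train = train_fm.samples()
            X_test = test_fm.samples()
        else:
            raise ValueError(f"unknown reduction {config.reduction!r}")

        if config.classifier == "knn":
            clf = train_knn(X_train, y_train, k=config.k)
        elif config.classifier in ("lda", "qda"):
            form = "linear" if config.classifier == "lda" else "quadratic"
            clf = train_da(X_train, y_train, form=form)
        elif config.classifier == "svm":
            clf = train_svm_ova(X_train, y_train, C=config.svm_C, gamma=config.svm_gamma)
        else:
            raise ValueError(f"unknown classifier {config.classifier!r}")

        pred = clf.predict(X_test)
        if config.apply_duration_filter:
            pred = duration_filter(LabelSeries(pred)).labels
        cm = confusion(y_test, pred, classes=classes)
        fold_cms.append(cm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_mets.append(metrics(cm))
        fold_subjects.append(test_fm.subject_id)

    pooled_cm = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled_cm = pooled_cm + cm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = metrics(pooled_cm)
    return LosoReport(
        pooled=pooled,
        pooled_confusion=pooled_cm,
        fold_confusions=fold_cms,
        fold_metrics=fold_mets,
        fold_subjects=fold_subjects,
        mean_wac=float(np.nanmean([fm.wac for fm in fold_mets])),
        mean_accuracy=float(np.mean([fm.accuracy for fm in fold_mets])),
    )


#: reduced 3x3 grid used for desk-scale parameter recovery; it subsamples the
#: full grid and brackets the operating points the full search favors
#: (C = 2^-1, gamma = 2^-1 and the small-C / small-gamma corner)
REDUCED_C_GRID = (2.0 ** -5, 2.0 ** -1, 2.0 ** 3)
REDUCED_GAMMA_GRID = (2.0 ** -9, 2.0 ** -5, 2.0 ** -1)


def svm_grid_search_loso(features_by_subject, labels_by_subject,
                         config: PipelineConfig | None = None,
                         C_grid=REDUCED_C_GRID,
                         gamma_grid=REDUCED_GAMMA_GRID) -> GridSearchResult:
    """Leave-one-subject-out SVM grid search with per-fold feature ranking.

    For every fold, conditioning and mRMR ranking (or PCA) are fitted on
    the training subjects only; the fold's reduced design matrices are
    then reused across all (C, gamma) pairs.  Each pair is scored by its
    mean duration-filtered WAC over folds; ties break toward smaller C,
    then smaller gamma.  This is the selection-by-outer-fold protocol;
    treat the returned ``best_wac`` as an optimistic model-selection
    summary, not an unbiased generalization estimate.
    """
    config = config or PipelineConfig(task="multiclass", classifier="svm",
                                      reduction="mrmr", n_features=40)
    m = len(features_by_subject)
    if m < 2:
        raise ValueError("grid search needs at least 2 subjects")
    if config.precondition:
        cond_cfg = ConditioningConfig()
        features_by_subject = [condition(fm, cond_cfg) for fm in features_by_subject]
    classes = np.array([0, 1]) if config.task == "binary" else np.array([0, 1, 2, 3])

    folds = []
    for hold in range(m):
        train_idx = [i for i in range(m) if i != hold]
        train_fm = concat_feature_matrices([features_by_subject[i] for i in train_idx])
        y_train = np.concatenate(
            [_task_labels(labels_by_subject[i], config.task) for i in train_idx])
        y_test = _task_labels(labels_by_subject[hold], config.task)
        if config.reduction == "mrmr":
            keep = mrmr_rank(train_fm, y_train).top(config.n_features)
            X_train = train_fm.samples(keep)
            X_test = features_by_subject[hold].samples(keep)
        elif config.reduction == "pca":
            model = pca_fit(train_fm, config.n_features)
            X_train = pca_transform(model, train_fm)
            X_test = pca_transform(model, features_by_subject[hold])
        else:
            X_train = train_fm.samples()
            X_test = features_by_subject[hold].samples()
        folds.append((X_train, y_train, X_test, y_test))

    results = []
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            wacs = []
            for X_train, y_train, X_test, y_test in folds:
                clf = train_svm_ova(X_train, y_train, C=C, gamma=gamma)
                pred = clf.predict(X_test)
                if config.apply_duration_filter:
                    pred = duration_filter(LabelSeries(pred)).labels
                cm = confusion(y_test, pred, classes=classes)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    wacs.append(metrics(cm).wac)
            results.append((C, gamma, float(np.nanmean(wacs))))
    best_C, best_gamma, best_wac = max(results, key=lambda r: (r[2], -r[0], -r[1]))
    return GridSearchResult(grid=results, best_C=best_C, best_gamma=best_gamma,
                            best_wac=best_wac)
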