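"""Five-emotion classification: segment-wise CV, normalization, LDA, metrics.

Cross-validation folds respect the temporal structure of the recording:
each emotion's contiguous segment is cut into k contiguous sub-segments
and fold j validates on one sub-segment per emotion, so temporally
adjacent (near-duplicate) frames never straddle the train/validation
boundary.  Per-fold, feature weights are learned by NCA on the training
rows only, features are selected, both sets are z-scored with training
statistics, and a shared-covariance LDA predicts the validation rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .features import feature_names
from .nca import NCAWeights, fit_nca, select_features, selection_frequency


@dataclass
class CVSplit:
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    #: per-segment chunk id validated by this fold, keyed by segment order
    sub_segments: dict = field(default_factory=dict)


def make_segment_splits(labels: Sequence, k: int = 3,
                        seed: int = 0) -> list[CVSplit]:
    """Contiguous sub-segment k-fold splits of labeled emotion frames.

    ``labels`` is the per-row emotion label in temporal order; maximal
    runs of one label form segments.  Each segment is cut into k
    contiguous chunks (sizes as equal as possible) and a seeded
    permutation assigns chunks to folds independently per segment.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if k < 2:
        raise ValueError(f"k must be >= 2 (no validation possible with k={k})")
    if n == 0:
        raise ValueError("no labeled rows")
    # maximal runs of constant label
    bounds = [0] + [i for i in range(1, n) if labels[i] != labels[i - 1]] + [n]
    segments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    rng = np.random.default_rng(seed)
    fold_val: list[list[np.ndarray]] = [[] for _ in range(k)]
    sub_assign: list[dict] = [dict() for _ in range(k)]
    for s, (a, b) in enumerate(segments):
        if b - a < k:
            raise ValueError(
                f"segment {s} ({labels[a]!r}) has {b - a} frames, fewer than k={k}")
        chunks = np.array_split(np.arange(a, b), k)
        perm = rng.permutation(k)
        for j in range(k):
            fold_val[j].append(chunks[perm[j]])
            sub_assign[j][s] = int(perm[j])
    splits = []
    all_idx = np.arange(n)
    for j in range(k):
        val = np.sort(np.concatenate(fold_val[j]))
        train = np.setdiff1d(all_idx, val)
        splits.append(CVSplit(j, train, val, sub_assign[j]))
    return splits


@dataclass(frozen=True)
class Normalizer:
    """Per-feature training mean/sd; sd of a constant feature is set to 1."""

    mean: np.ndarray
    sd: np.ndarray


def fit_normalizer(train: np.ndarray) -> Normalizer:
    train = np.asarray(train, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need >= 2 training rows to fit a normalizer")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return Normalizer(mean=mean, sd=sd)


def apply_normalizer(X: np.ndarray, norm: Normalizer) -> np.ndarray:
    return (np.asarray(X, dtype=np.float64) - norm.mean) / norm.sd


def lda_fit(train: np.ndarray, labels: Sequence,
            shrinkage: float = 1e-6) -> LinearDiscriminantAnalysis:
    """Shared-covariance multiclass LDA with uniform priors.

    Shrinkage regularizes the pooled covariance toward a scaled
    identity, keeping the fit defined when the covariance is singular.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes in the training set")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 training rows")
    model = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=shrinkage,
        priors=np.full(classes.size, 1.0 / classes.size))
    model.fit(np.asarray(train, dtype=np.float64), labels)
    return model


def lda_predict(model: LinearDiscriminantAnalysis, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=np.float64))


@dataclass
class ClassificationReport:
    """Confusion matrix and derived one-vs-rest metrics."""

    labels: tuple
    confusion: np.ndarray  # rows = truth, cols = prediction
    per_class: pd.DataFrame  # accuracy, tpr, fpr per class
    accuracy: float
    kappa: float

    def summary(self) -> str:
        lines = [f"overall accuracy: {self.accuracy:.4f}   "
                 f"Cohen's kappa: {self.kappa:.4f}",
                 self.per_class.to_string(float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)


def evaluate(y_true: Sequence, y_pred: Sequence,
             labels: Sequence | None = None) -> ClassificationReport:
    """One-vs-rest accuracy/TPR/FPR per class, overall accuracy and kappa."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("empty or mismatched prediction/truth vectors")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = list(labels)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    total = cm.sum()
    rows = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[lab] = {
            "accuracy": (tp + tn) / total,
            "tpr": tp / (tp + fn) if tp + fn else np.nan,
            "fpr": fp / (fp + tn) if fp + tn else np.nan,
        }
    return ClassificationReport(
        labels=tuple(labels),
        confusion=cm,
        per_class=pd.DataFrame.from_dict(rows, orient="index"),
        accuracy=float(np.trace(cm) / total),
        kappa=float(cohen_kappa_score(y_true, y_pred, labels=labels)),
    )


@dataclass
class PipelineResult:
    """Everything produced by one cross-validated classification run."""

    report: ClassificationReport
    fold_reports: list[ClassificationReport]
    fold_selected: list[np.ndarray]  # selected feature indices per fold
    fold_weights: list[NCAWeights]
    frequency: pd.DataFrame  # ROI x feature selection counts
    splits: list[CVSplit]


def _stratified_subsample(y: np.ndarray, max_n: int,
                          rng: np.random.Generator) -> np.ndarray:
    n = y.size
    if n <= max_n:
        return np.arange(n)
    keep = []
    classes = np.unique(y)
    per = max(2, max_n // classes.size)
    for c in classes:
        idx = np.nonzero(y == c)[0]
        keep.append(rng.choice(idx, size=min(per, idx.size), replace=False))
    return np.sort(np.concatenate(keep))


def run_classification_pipeline(
    features_df: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    *,
    sigma: float = 1.0,
    lam: float | None = None,
    tau: float = 0.1,
    max_nca_samples: int = 200,
    nca_max_iter: int = 50,
    nca_tol: float = 1e-4,
    shrinkage: float = 1e-6,
    baseline_label: str = "baseline",
    permute_labels: bool = False,
    feature_cols: Sequence[str] | None = None,
) -> PipelineResult:
    """Segment-wise k-fold NCA + LDA classification of the five emotions.

    Baseline rows are excluded (they are the statistics module's
    reference, not a sixth class).  Per fold: z-score with training
    statistics, fit NCA on a stratified training subsample (at most
    ``max_nca_samples`` rows), select features with threshold ``tau``,
    fit LDA on the selected standardized training features, predict the
    validation rows.  ``permute_labels=True`` replaces the labels by a
    seeded permutation (keeping segment geometry for the splits): a
    chance-level control.
    """
    if feature_cols is None:
        feature_cols = [c for c in feature_names() if c in features_df.columns]
        if not feature_cols:
            raise ValueError("no canonical feature columns in features_df")
    rows = features_df[features_df["label"] != baseline_label].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no emotion-labeled rows to classify")
    X = rows[list(feature_cols)].to_numpy(dtype=np.float64)
    y = rows["label"].to_numpy(dtype=object)

    rng = np.random.default_rng(seed)
    splits = make_segment_splits(y, k=k, seed=int(rng.integers(2**31)))
    if permute_labels:
        y = y[rng.permutation(y.size)]

    labels_order = sorted(set(y))
    y_true_all: list = []
    y_pred_all: list = []
    fold_reports, fold_selected, fold_weights = [], [], []
    for split in splits:
        Xtr, ytr = X[split.train_idx], y[split.train_idx]
        Xval, yval = X[split.val_idx], y[split.val_idx]
        norm = fit_normalizer(Xtr)
        Ztr = apply_normalizer(Xtr, norm)
        Zval = apply_normalizer(Xval, norm)
        sub = _stratified_subsample(ytr, max_nca_samples, rng)
        weights = fit_nca(Ztr[sub], ytr[sub], sigma=sigma, lam=lam,
                          max_iter=nca_max_iter, tol=nca_tol)
        sel = select_features(weights, tau=tau)
        model = lda_fit(Ztr[:, sel], ytr, shrinkage=shrinkage)
        pred = lda_predict(model, Zval[:, sel])
        fold_reports.append(evaluate(yval, pred, labels=labels_order))
        fold_selected.append(sel)
        fold_weights.append(weights)
        y_true_all.append(yval)
        y_pred_all.append(pred)

    report = evaluate(np.concatenate(y_true_all), np.concatenate(y_pred_all),
                      labels=labels_order)
    names = [feature_cols[i] for i in range(len(feature_cols))]
    freq = selection_frequency([sel for sel in fold_selected], names=names)
    return PipelineResult(report=report, fold_reports=fold_reports,
                          fold_selected=fold_selected,
                          fold_weights=fold_weights,
                          frequency=freq, splits=splits)
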