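"""Balanced linear discriminant classification and ROC evaluation.

Classes are balanced by undersampling the majority class before every fit,
so the discriminant uses equal priors.  Per-segment performance is read
off the ROC at the operating point closest to the upper-left corner
(FPR=0, TPR=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve


def undersample(
    features: np.ndarray, labels: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly subsample the majority class down to the minority count."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling requires both classes present")
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    return np.asarray(features)[sel], labels[sel]


@dataclass
class LdaModel:
    """Two-class linear discriminant with pooled covariance.

    ``score = x @ w + b`` with ``w = Sigma^-1 (mu1 - mu0)``; higher scores
    mean more apneic.  A ridge term ``lam`` on the covariance diagonal
    guards against singularity.
    """

    means: np.ndarray          # (2, p): class 0 then class 1
    pooled_cov: np.ndarray     # (p, p) after regularization
    prior_logodds: float
    feature_names: list[str] | None = None
    weights: np.ndarray = field(init=False)
    bias: float = field(init=False)

    def __post_init__(self) -> None:
        diff = self.means[1] - self.means[0]
        self.weights = np.linalg.solve(self.pooled_cov, diff)
        mid = 0.5 * (self.means[0] + self.means[1])
        self.bias = float(-mid @ self.weights + self.prior_logodds)


def lda_fit(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.0,
    feature_names: list[str] | None = None,
) -> LdaModel:
    """Fit the discriminant; retries with a small ridge if the pooled
    covariance is singular."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("LDA fit requires exactly two classes")
    n0, n1 = (y == classes[0]).sum(), (y == classes[1]).sum()
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 samples per class")
    mu = np.vstack([x[y == c].mean(axis=0) for c in classes])
    p = x.shape[1]
    scatter = np.zeros((p, p))
    for i, c in enumerate(classes):
        xc = x[y == c] - mu[i]
        scatter += xc.T @ xc
    cov = scatter / (x.shape[0] - 2) + lam * np.eye(p)
    prior_logodds = float(np.log(n1 / n0))
    try:
        np.linalg.cholesky(cov + 1e-300 * np.eye(p))
        model = LdaModel(mu, cov, prior_logodds, feature_names)
    except np.linalg.LinAlgError:
        model = None
    if model is None or not np.isfinite(model.weights).all():
        warnings.warn("singular pooled covariance: applying ridge lam=1e-6")
        cov = scatter / (x.shape[0] - 2) + 1e-6 * np.eye(p)
        model = LdaModel(mu, cov, prior_logodds, feature_names)
    return model


def lda_score(model: LdaModel, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    return x @ model.weights + model.bias


@dataclass
class SegmentMetrics:
    accuracy: float     # %
    sensitivity: float  # %
    specificity: float  # %
    auc: float
    roc: tuple[np.ndarray, np.ndarray]  # (FPR, TPR)
    threshold_at_op: float


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) predicting positive when score >= threshold."""
    pred = np.asarray(scores) >= threshold
    truth = np.asarray(labels).astype(bool)
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    return tp, tn, fp, fn


def roc_and_operating_point(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
) -> SegmentMetrics:
    """ROC sweep, trapezoid AUC and corner-closest operating point.

    When ``threshold`` is given (tuned elsewhere, e.g. on the learning
    set) the confusion metrics are computed at that score cut instead of
    re-tuning on the evaluation data; the ROC and AUC always describe the
    evaluation scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = auc_trapezoid(fpr, tpr)
    if threshold is None:
        dist = np.sqrt(fpr**2 + (1 - tpr) ** 2)
        i = int(np.argmin(dist))
        # sklearn reports the threshold *above* which... it uses >=; its
        # first threshold is inf for the (0,0) point
        threshold = float(thr[i]) if np.isfinite(thr[i]) else float(scores.max() + 1)
    tp, tn, fp, fn = confusion_at_threshold(scores, labels, threshold)
    pos, neg = tp + fn, tn + fp
    return SegmentMetrics(
        accuracy=100.0 * (tp + tn) / (pos + neg),
        sensitivity=100.0 * tp / pos if pos else 0.0,
        specificity=100.0 * tn / neg if neg else 0.0,
        auc=auc,
        roc=(fpr, tpr),
        threshold_at_op=float(threshold),
    )
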