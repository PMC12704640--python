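"""The DESI ratio, threshold classification and evaluation metrics.

DESI (Disproportionately Elevated Sulcal Index) is the dimensionless ratio
of Sylvian fissure CSF volume to the wedge-restricted superior sulcal CSF
volume.  High values indicate the DESH pattern (enlarged Sylvian fissures
with tight high-convexity sulci).  Published operating points for the
ratio: 6.10 for DESH vs non-DESH hydrocephalus, 4.83 for DESH vs all other
diagnostic groups, 1.92 for hydrocephalus vs everyone else; the decision
rule is score >= threshold => positive.

Also provided: the segmentation/landmark evaluation metrics (3D Dice,
exact symmetric Hausdorff distance in mm, Euclidean landmark error) and
cohort-level ROC/AUC utilities, including an sklearn-style
:class:`DesiThresholdClassifier`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .volumetrics import VolumeReport


@dataclass(frozen=True)
class ClassifierConfig:
    """Named DESI decision thresholds (score >= threshold => positive)."""

    desh_vs_nondesh_nph: float = 6.10
    desh_vs_other_groups: float = 4.83
    nph_vs_all: float = 1.92

    def __post_init__(self):
        if min(asdict(self).values()) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DesiResult:
    sylvian_total_mm3: float
    superior_wedge_mm3: float
    desi: float                      # nan when undefined (zero denominator)
    defined: bool = True
    threshold_used: float = None
    label: str = None                # 'positive' / 'negative'

    def to_dict(self) -> dict:
        return asdict(self)


def compute_desi(report: VolumeReport) -> DesiResult:
    """Ratio of Sylvian to wedge-restricted superior sulcal volume.

    A zero superior volume yields an explicitly undefined result (flagged,
    ratio nan) rather than a silent infinity — clinically it is the extreme
    of disproportion, and :func:`classify_desi` treats it as positive.
    """
    syl = float(report.sylvian_total_mm3)
    sup = float(report.superior_wedge_mm3)
    if syl < 0 or sup < 0:
        raise ValueError("volumes must be nonnegative")
    if sup == 0:
        return DesiResult(syl, sup, float("nan"), defined=False)
    return DesiResult(syl, sup, syl / sup, defined=True)


def classify_desi(result, threshold: float):
    """Label a DESI value against a threshold (>= is positive).

    Accepts a :class:`DesiResult` or a bare ratio.  An undefined index
    (zero superior volume) classifies positive with a warning.
    """
    if isinstance(result, DesiResult):
        if not result.defined:
            warnings.warn("undefined DESI (zero superior sulcal volume); "
                          "classifying as positive")
            result.threshold_used = float(threshold)
            result.label = "positive"
            return result
        value = result.desi
    else:
        value = float(result)
        result = None
    label = "positive" if value >= threshold else "negative"
    if result is not None:
        result.threshold_used = float(threshold)
        result.label = label
        return result
    return label


@dataclass
class ClassificationMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    auc: float = None
    threshold: float = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int,
                      auc: float = None, threshold: float = None
                      ) -> ClassificationMetrics:
    """Sensitivity, specificity, precision, F1 and accuracy from counts.

    Fractions are exact; round only at display time.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative case")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / (tp + fn + tn + fp)
    return ClassificationMetrics(tp, fn, tn, fp, sens, spec, prec, f1, acc,
                                 auc=auc, threshold=threshold)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic.

    Equal to P(score_pos > score_neg) + 0.5 P(tie), i.e. the trapezoidal
    area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def best_threshold(scores, labels):
    """Threshold maximizing Youden's J (sensitivity + specificity - 1).

    Candidates are the midpoints of adjacent sorted unique scores; ties on J
    break toward the smallest threshold.  With a single unique score that
    score itself is returned (J = 0 everywhere).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_cohort(scores, labels, threshold: float = None
                    ) -> ClassificationMetrics:
    """AUC plus confusion metrics at a fixed or Youden-optimal threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = roc_auc(scores, labels)
    t = best_threshold(scores, labels) if threshold is None else float(threshold)
    pred = scores >= t
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    return confusion_metrics(tp, fn, tn, fp, auc=auc, threshold=t)


class DesiThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Threshold rule on a scalar score, sklearn-style.

    With ``threshold=None`` the Youden-optimal threshold is learned by
    ``fit``; with a numeric threshold (e.g. the published 4.83 operating
    point) ``fit`` only validates input.  Predicts 1 where
    score >= ``threshold_``.
    """

    def __init__(self, threshold: float = None):
        self.threshold = threshold

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expects a single score feature")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.array([0, 1])
        if self.threshold is None:
            self.threshold_ = best_threshold(s, y)
        else:
            self.threshold_ = float(self.threshold)
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        return self._scores(X) - self.threshold_

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


# --- segmentation / landmark evaluation -------------------------------------

def dice_3d(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A^B| / (|A|+|B|); two empty masks agree (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    surf = mask & ~eroded
    pts = np.argwhere(surf).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def hausdorff_mm(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0),
                 percentile: float = None) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in mm.

    Exact maximum by default; ``percentile`` (e.g. 95) gives the robust
    percentile variant.  Distances are between surface-voxel centres.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    pa = _surface_points_mm(a, spacing)
    pb = _surface_points_mm(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def landmark_error_mm(pred, truth) -> float:
    """Euclidean distance in mm between predicted and true landmark."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.linalg.norm(pred - truth))
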