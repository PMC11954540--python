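"""Statistical evaluation of anomaly scores.

ROC and PR curves with AUC / average precision, leave-one-volume-out PPV and
NPV with optimal-cutoff transfer, relative-position anomaly profiles, and
anomaly-map severity scores with Pearson and Spearman correlations.

Curve construction stands on scikit-learn; AP is the step-weighted mean of
precisions (not a trapezoidal area). The optimal ROC cutoff is the swept
threshold whose (FPR, TPR) point lies closest to the ideal corner (0, 1),
ties broken toward the higher threshold (fewer samples flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

__all__ = [
    "LabeledScores",
    "CurveResult",
    "LooResult",
    "SeverityRecord",
    "roc_curve_auc",
    "pr_curve_ap",
    "optimal_cutoff",
    "loo_ppv_npv",
    "anomaly_profile",
    "severity_scores",
    "training_threshold",
]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with binary labels (1 = anomalous) and optional volume ids."""

    scores: np.ndarray
    labels: np.ndarray
    group_id: Optional[np.ndarray] = None

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=int)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0 normal, 1 anomalous)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if self.group_id is not None:
            gid = np.asarray(self.group_id)
            if gid.shape != scores.shape:
                raise ValueError("group_id must match scores length")
            object.__setattr__(self, "group_id", gid)


@dataclass(frozen=True)
class CurveResult:
    """A swept curve (ROC or PR) and its summary area."""

    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: float
    kind: str = "roc"


@dataclass(frozen=True)
class SeverityRecord:
    slice_id: str
    relative_lesion_area: float
    map_score: float


@dataclass
class LooResult:
    per_volume: pd.DataFrame  # columns: volume_id, ppv, npv, threshold, tp, fp, tn, fn
    ppv_mean: float
    ppv_sd: float
    npv_mean: float
    npv_sd: float
    n_missing_ppv: int
    n_missing_npv: int
    skipped_folds: list


def _require_both_classes(labels: np.ndarray, context: str):
    if labels.min() == labels.max():
        raise ValueError(f"{context}: both classes must be present")


def roc_curve_auc(data: LabeledScores) -> CurveResult:
    """ROC curve (FPR, TPR) over the swept thresholds and its AUC.

    The AUC equals the Mann-Whitney concordance
    P(score_anom > score_norm) + 0.5 * P(tie).
    """
    _require_both_classes(data.labels, "ROC")
    fpr, tpr, thr = roc_curve(data.labels, data.scores)
    return CurveResult(thresholds=thr, x=fpr, y=tpr, area=float(_sk_auc(fpr, tpr)), kind="roc")


def pr_curve_ap(data: LabeledScores) -> CurveResult:
    """PR curve and average precision (step-weighted mean of precisions)."""
    if data.labels.sum() == 0:
        raise ValueError("PR curve requires at least one positive")
    precision, recall, thr = precision_recall_curve(data.labels, data.scores)
    ap = float(average_precision_score(data.labels, data.scores))
    return CurveResult(thresholds=thr, x=recall, y=precision, area=ap, kind="pr")


def optimal_cutoff(curve: CurveResult) -> float:
    """Threshold whose ROC point is closest to (0, 1); ties -> higher threshold."""
    if curve.kind != "roc":
        raise ValueError("optimal_cutoff expects a ROC CurveResult")
    d2 = curve.x ** 2 + (1.0 - curve.y) ** 2
    best = d2.min()
    candidates = np.flatnonzero(np.isclose(d2, best))
    # sklearn thresholds are decreasing, so the smallest index is the highest
    return float(curve.thresholds[candidates.min()])


def _binarize_counts(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def loo_ppv_npv(data: LabeledScores) -> LooResult:
    """Leave-one-volume-out PPV/NPV with optimal-cutoff transfer.

    For each volume: build one ROC on all other volumes' B-scans, take the
    optimal cutoff, binarize the held-out volume's scores with it, and report
    PPV = TP/(TP+FP) and NPV = TN/(TN+FN). Zero-denominator ratios are
    missing (NaN) and excluded from the summary means; folds whose training
    scores are single-class are skipped with a warning.
    """
    if data.group_id is None:
        raise ValueError("loo_ppv_npv requires group_id (volume ids)")
    volumes = pd.unique(data.group_id)
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes for leave-one-out")
    rows = []
    skipped = []
    for vol in volumes:
        held = data.group_id == vol
        train_labels = data.labels[~held]
        if train_labels.min() == train_labels.max():
            skipped.append(vol)
            warnings.warn(f"fold {vol!r} skipped: single-class training scores", stacklevel=2)
            continue
        curve = roc_curve_auc(LabeledScores(data.scores[~held], train_labels))
        thr = optimal_cutoff(curve)
        tp, fp, tn, fn = _binarize_counts(data.scores[held], data.labels[held], thr)
        ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        npv = tn / (tn + fn) if (tn + fn) > 0 else np.nan
        rows.append({"volume_id": vol, "ppv": ppv, "npv": npv, "threshold": thr,
                     "tp": tp, "fp": fp, "tn": tn, "fn": fn})
    per_volume = pd.DataFrame(rows)
    ppv = per_volume["ppv"].to_numpy(dtype=float)
    npv = per_volume["npv"].to_numpy(dtype=float)
    return LooResult(
        per_volume=per_volume,
        ppv_mean=float(np.nanmean(ppv)) if np.any(~np.isnan(ppv)) else np.nan,
        ppv_sd=float(np.nanstd(ppv, ddof=1)) if np.sum(~np.isnan(ppv)) > 1 else np.nan,
        npv_mean=float(np.nanmean(npv)) if np.any(~np.isnan(npv)) else np.nan,
        npv_sd=float(np.nanstd(npv, ddof=1)) if np.sum(~np.isnan(npv)) > 1 else np.nan,
        n_missing_ppv=int(np.sum(np.isnan(ppv))),
        n_missing_npv=int(np.sum(np.isnan(npv))),
        skipped_folds=skipped,
    )


def interp_profile(scores: Sequence[float], target_length: int) -> np.ndarray:
    """Linearly interpolate one volume's slice scores onto ``target_length``
    equispaced relative positions in [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("profile needs at least 2 slices")
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    pos = np.linspace(0.0, 1.0, scores.size)
    target = np.linspace(0.0, 1.0, target_length)
    return np.interp(target, pos, scores)


def anomaly_profile(volume_profiles: Sequence[Sequence[float]], target_length: int = 100,
                    classes: Optional[Sequence[str]] = None):
    """Mean anomaly-score profile over relative B-scan position.

    Each volume's score sequence is interpolated to ``target_length`` points;
    the pointwise mean is returned. With ``classes`` given (one label per
    volume), returns a dict mapping class -> mean profile.
    """
    if len(volume_profiles) == 0:
        raise ValueError("no volumes given")
    interped = np.stack([interp_profile(p, target_length) for p in volume_profiles])
    if classes is None:
        return interped.mean(axis=0)
    classes = np.asarray(classes)
    if classes.shape[0] != interped.shape[0]:
        raise ValueError("classes must have one entry per volume")
    return {str(c): interped[classes == c].mean(axis=0) for c in pd.unique(classes)}


def training_threshold(train_maps: Sequence[np.ndarray]) -> float:
    """Pixel-weighted mean of all anomaly-map values over the training set.

    This is the data-driven activation threshold used by severity scoring
    (the analogue of a fixed 'average training anomaly score').
    """
    if len(train_maps) == 0:
        raise ValueError("no training maps given")
    total = 0.0
    count = 0
    for m in train_maps:
        m = np.asarray(m, dtype=np.float64)
        total += m.sum()
        count += m.size
    return float(total / count)


def severity_scores(maps: Sequence[np.ndarray], masks: Sequence[np.ndarray], threshold: float,
                    slice_ids: Optional[Sequence[str]] = None):
    """Per-slice severity pairs and their correlations.

    map_score = mean of anomaly-map values strictly greater than ``threshold``
    (0 when none exceed it); relative_lesion_area = positive mask pixels /
    slice pixels. Returns ``(records, (pearson_r, spearman_rho))``;
    correlations are NaN when either series is constant.
    """
    if len(maps) != len(masks):
        raise ValueError("maps and masks must have equal length")
    if slice_ids is None:
        slice_ids = [str(i) for i in range(len(maps))]
    records: List[SeverityRecord] = []
    for sid, m, msk in zip(slice_ids, maps, masks):
        m = np.asarray(m, dtype=np.float64)
        msk = np.asarray(msk)
        if m.shape != msk.shape:
            raise ValueError(f"map/mask shape mismatch for slice {sid}: {m.shape} vs {msk.shape}")
        above = m[m > threshold]
        map_score = float(above.mean()) if above.size else 0.0
        records.append(SeverityRecord(slice_id=str(sid),
                                      relative_lesion_area=float((msk > 0).sum() / msk.size),
                                      map_score=map_score))
    areas = np.array([r.relative_lesion_area for r in records])
    mscores = np.array([r.map_score for r in records])
    if np.ptp(areas) == 0 or np.ptp(mscores) == 0 or len(records) < 2:
        return records, (float("nan"), float("nan"))
    pearson = float(stats.pearsonr(areas, mscores).statistic)
    spearman = float(stats.spearmanr(areas, mscores).statistic)
    return records, (pearson, spearman)
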