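"""Agreement, ROC/AUC and DeLong comparison of correlated AUCs.

Scoring conventions:

* a whole image is positive if *any* of its six segments is positive
  (logical OR of labels); the continuous whole-image machine score is the
  maximum over the six segment scores;
* agreement is the percentage of matching binary decisions, at per-segment
  (all 6n decisions), per-image, or per-segment-index granularity;
* AUC follows the Mann–Whitney pairwise convention (ties count ½), which is
  what thresholding the scores over [0, 1] integrates to;
* two AUCs measured on the same cases are compared with the DeLong test,
  which accounts for their correlation via placement values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .phantom import N_SEGMENTS

__all__ = [
    "RocResult",
    "DelongResult",
    "whole_image_label",
    "whole_image_score",
    "binarise",
    "agreement",
    "roc_auc",
    "delong_compare",
    "pairwise_agreement_matrix",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float | None
    p_two_sided: float


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def whole_image_label(segment_labels) -> int:
    """A T1 map is motion-positive if at least one segment is positive."""
    labels = _check_binary(segment_labels, "segment_labels")
    if labels.shape[-1] != N_SEGMENTS:
        raise ValueError("expected 6 segment labels")
    return (
        labels.any(axis=-1).astype(int)
        if labels.ndim > 1
        else int(labels.any())
    )


def whole_image_score(segment_scores) -> np.ndarray:
    """Continuous analogue of the OR rule: the max over segment scores."""
    scores = np.asarray(segment_scores, dtype=float)
    return scores.max(axis=-1)


def binarise(scores, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def agreement(pred_binary, labels, level: str = "per_segment"):
    """Percentage of matching binary decisions.

    ``per_segment`` pools all 6n decisions; ``per_image`` applies the OR rule
    to both tables first; ``per_segment_index`` returns six percentages, one
    per AHA segment.
    """
    pred = _check_binary(pred_binary, "pred")
    lab = _check_binary(labels, "labels")
    if pred.shape != lab.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {lab.shape}")
    if level == "per_segment":
        return float((pred == lab).mean() * 100.0)
    if level == "per_image":
        return float(
            (whole_image_label(pred) == whole_image_label(lab)).mean() * 100.0
        )
    if level == "per_segment_index":
        if pred.ndim != 2 or pred.shape[1] != N_SEGMENTS:
            raise ValueError("per_segment_index needs an (n, 6) table")
        return (pred == lab).mean(axis=0) * 100.0
    raise ValueError(f"unknown level {level!r}")


def roc_auc(scores, labels) -> RocResult:
    """ROC curve by thresholding scores over [0, 1]; AUC with midrank ties."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels, "labels").ravel()
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, thr = skmetrics.roc_curve(labels, scores)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=float(skmetrics.roc_auc_score(labels, scores)))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values via midranks: V10 (per positive), V01 (per
    negative), and the AUC (their common mean)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_compare(scores_a, scores_b, labels) -> DelongResult:
    """DeLong test for two correlated AUCs measured on the same cases.

    Variance of ΔAUC combines the per-class covariance matrices of the
    placement values; z = ΔAUC / SE with a two-sided normal p-value.  When
    the variance is degenerate (e.g. identical score tables), ΔAUC = 0 maps
    to p = 1 and a nonzero ΔAUC is flagged with z = None, p = NaN.
    """
    scores_a = np.asarray(scores_a, dtype=float).ravel()
    scores_b = np.asarray(scores_b, dtype=float).ravel()
    labels = _check_binary(labels, "labels").ravel()
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores and labels must be aligned")
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: both classes must be present")

    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = auc_a - auc_b
    if var <= 0:
        if delta == 0:
            return DelongResult(auc_a, auc_b, 0.0, float(var), None, 1.0)
        return DelongResult(auc_a, auc_b, delta, float(var), None, float("nan"))
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, delta, float(var), float(z), p)


def pairwise_agreement_matrix(
    rater_tables: dict[str, np.ndarray] | list[np.ndarray],
    level: str = "per_segment",
) -> pd.DataFrame:
    """Symmetric matrix of agreement percentages between every rater pair.

    Each table is an aligned (n, 6) binary array (machine scores should be
    binarised first).  ``level`` is per_segment or per_image.
    """
    if isinstance(rater_tables, dict):
        names = list(rater_tables)
        tables = [rater_tables[k] for k in names]
    else:
        names = [f"rater{i}" for i in range(len(rater_tables))]
        tables = list(rater_tables)
    if len(tables) < 2:
        raise ValueError("need at least two raters")
    shapes = {np.asarray(t).shape for t in tables}
    if len(shapes) != 1:
        raise ValueError("rater tables must be aligned")
    k = len(tables)
    out = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            a = agreement(tables[i], tables[j], level=level)
            out[i, j] = out[j, i] = a
    return pd.DataFrame(out, index=names, columns=names)
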