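"""Zone-to-image aggregation and support-weighted multiclass metrics.

The image-level ILO category is the maximum of the six zone categories
(e.g. zones [RUZ:1, RMZ:0, RLZ:0, LUZ:2, LMZ:1, LLZ:0] give category 2).
Binary detection is derived from the multiclass label: category 0 is
negative, categories 1-3 are positive.

Metrics are one-vs-rest per class k from the confusion matrix:

    ACC_k = (TP + TN) / N      SEN_k = TP / (TP + FN)
    SPE_k = TN / (TN + FP)     F1_k  = 2 TP / (2 TP + FP + FN)

and reported as support-weighted averages (weights = true-class counts).
Note the identity: support-weighted SEN equals the plain multiclass
accuracy trace/N — this is why binary detection tables show identical ACC
and SEN columns, while the reported multiclass ACC (a weighted mean of
one-vs-rest accuracies) is higher. One-vs-rest AUC per class is computed by
a rank (Mann-Whitney) statistic, equivalent to a threshold sweep over all
distinct scores, and weighted the same way. Undefined 0/0 cells are set to
0 with a warning; zero-support classes get weight 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CoverageError, ParameterError
from .zones import ZONE_NAMES

logger = logging.getLogger(__name__)


def aggregate_image_label(zone_labels: Mapping[str, int]) -> int:
    """Image-level ILO category: the maximum of the six zone categories."""
    missing = set(ZONE_NAMES) - set(zone_labels)
    if missing:
        raise CoverageError(f"missing zone labels: {sorted(missing)}")
    return int(max(int(zone_labels[z]) for z in ZONE_NAMES))


def binarize_detection(image_category: int) -> str:
    """Detection outcome: category 0 -> 'negative', categories 1-3 -> 'positive'."""
    if image_category not in (0, 1, 2, 3):
        raise ParameterError(f"category must be in 0..3, got {image_category}")
    return "negative" if image_category == 0 else "positive"


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ParameterError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= n_classes):
        raise ParameterError(f"labels out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def per_class_counts(cm: np.ndarray) -> Dict[str, np.ndarray]:
    """One-vs-rest TP/FN/FP/TN per class from a confusion matrix."""
    cm = np.asarray(cm)
    n = cm.sum()
    tp = np.diag(cm).astype(int)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp
    return {"tp": tp, "fn": fn, "fp": fp, "tn": tn}


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if (~ok).any():
        logger.warning("%s: 0/0 for class(es) %s, defined as 0", name, np.where(~ok)[0].tolist())
    return out


def roc_auc_binary(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC for one binary problem (rank statistic, tie-aware)."""
    y = np.asarray(y_true, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC undefined: one class absent")
    ranks = rankdata(np.asarray(scores, dtype=float))
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Support-weighted metric summary plus the per-class breakdown."""

    acc: float
    sen: float
    spe: float
    f1: float
    auc: Optional[float]
    per_class: Dict[int, Dict[str, float]]
    n: int
    averaging: str = "weighted"

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "f1": self.f1,
            "auc": self.auc,
            "n": self.n,
            "averaging": self.averaging,
            "per_class": {int(k): v for k, v in self.per_class.items()},
        }


def weighted_metrics(
    cm: np.ndarray,
    probabilities: Optional[np.ndarray] = None,
    y_true: Optional[Sequence[int]] = None,
) -> MetricsReport:
    """Support-weighted one-vs-rest metrics from a confusion matrix.

    If per-sample probability vectors and true labels are supplied, a
    support-weighted one-vs-rest AUC is included (classes with zero support
    or full support are skipped with weight 0).
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ParameterError("confusion matrix must be square and non-negative")
    k = cm.shape[0]
    n = int(cm.sum())
    counts = per_class_counts(cm)
    tp, fn, fp, tn = counts["tp"], counts["fn"], counts["fp"], counts["tn"]
    support = cm.sum(axis=1).astype(float)
    if support.sum() == 0:
        raise ParameterError("empty confusion matrix")
    weights = support / support.sum()
    if (support == 0).any():
        logger.warning("zero-support class(es) %s get weight 0", np.where(support == 0)[0].tolist())

    sen = _safe_ratio(tp, tp + fn, "SEN")
    spe = _safe_ratio(tn, tn + fp, "SPE")
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1")
    acc = (tp + tn) / float(n)

    auc_value = None
    auc_per_class = np.full(k, np.nan)
    if probabilities is not None:
        if y_true is None:
            raise ParameterError("y_true is required to compute AUC from probabilities")
        probs = np.asarray(probabilities, dtype=float)
        yt = np.asarray(y_true, dtype=int)
        if probs.shape != (len(yt), k):
            raise ParameterError(f"probabilities must be (n_samples, {k})")
        auc_weights = weights.copy()
        for c in range(k):
            pos = yt == c
            if 0 < pos.sum() < len(yt):
                auc_per_class[c] = roc_auc_binary(pos, probs[:, c])
            else:
                auc_weights[c] = 0.0
        if auc_weights.sum() > 0:
            auc_weights = auc_weights / auc_weights.sum()
            auc_value = float(np.nansum(auc_weights * np.nan_to_num(auc_per_class)))

    per_class = {
        c: {
            "tp": int(tp[c]), "tn": int(tn[c]), "fp": int(fp[c]), "fn": int(fn[c]),
            "support": int(support[c]),
            "acc": float(acc[c]), "sen": float(sen[c]), "spe": float(spe[c]), "f1": float(f1[c]),
            "auc": (None if np.isnan(auc_per_class[c]) else float(auc_per_class[c])),
        }
        for c in range(k)
    }
    return MetricsReport(
        acc=float(weights @ acc),
        sen=float(weights @ sen),
        spe=float(weights @ spe),
        f1=float(weights @ f1),
        auc=auc_value,
        per_class=per_class,
        n=n,
    )


def _prob_columns(frame: pd.DataFrame) -> list:
    cols = [c for c in frame.columns if c.startswith("p") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def evaluate_run(
    zone_predictions: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
) -> Tuple[Dict[str, MetricsReport], MetricsReport]:
    """Zone-level and image-level metric reports for one prediction set.

    ``zone_predictions`` maps each of the six zone names to a frame with
    columns ``image_id, zone_name, p0..p{K-1}, predicted``. All six frames
    must cover the same image ids. The image-level prediction is the max of
    the six predicted zone categories; the image-level probability vector
    (for AUC only) is the per-class maximum over zones, renormalised to the
    simplex.
    """
    missing = set(ZONE_NAMES) - set(zone_predictions)
    if missing:
        raise CoverageError(f"missing zone prediction tables: {sorted(missing)}")
    id_sets = {z: frozenset(f["image_id"]) for z, f in zone_predictions.items()}
    ids = id_sets[ZONE_NAMES[0]]
    for z, s in id_sets.items():
        if s != ids:
            raise CoverageError(f"image_id set of zone {z} differs from {ZONE_NAMES[0]}")

    man = manifest.set_index("image_id")
    extra = ids - set(man.index)
    if extra:
        raise CoverageError(f"predictions contain image ids absent from the manifest: {sorted(extra)[:5]}")
    order = [i for i in man.index if i in ids]

    zone_reports: Dict[str, MetricsReport] = {}
    pred_by_zone: Dict[str, pd.Series] = {}
    probs_by_zone: Dict[str, np.ndarray] = {}
    n_classes = None
    for zone in ZONE_NAMES:
        frame = zone_predictions[zone].set_index("image_id").loc[order]
        pcols = _prob_columns(frame)
        n_classes = len(pcols)
        y_true = man.loc[order, zone].to_numpy(dtype=int)
        y_pred = frame["predicted"].to_numpy(dtype=int)
        probs = frame[pcols].to_numpy(dtype=float)
        cm = confusion(y_true, y_pred, n_classes)
        zone_reports[zone] = weighted_metrics(cm, probabilities=probs, y_true=y_true)
        pred_by_zone[zone] = pd.Series(y_pred, index=order)
        probs_by_zone[zone] = probs

    image_true = man.loc[order, "image_label"].to_numpy(dtype=int)
    image_pred = np.max(np.stack([pred_by_zone[z].to_numpy() for z in ZONE_NAMES]), axis=0)
    stacked = np.stack([probs_by_zone[z] for z in ZONE_NAMES])     # (6, N, K)
    image_probs = stacked.max(axis=0)
    image_probs = image_probs / image_probs.sum(axis=1, keepdims=True)
    cm = confusion(image_true, image_pred, n_classes)
    image_report = weighted_metrics(cm, probabilities=image_probs, y_true=image_true)
    return zone_reports, image_report


def binary_report(image_true: Sequence[int], image_pred: Sequence[int],
                  positive_scores: Optional[np.ndarray] = None) -> MetricsReport:
    """Detection metrics from multiclass image labels (category >= 1 is positive)."""
    yt = (np.asarray(image_true, dtype=int) > 0).astype(int)
    yp = (np.asarray(image_pred, dtype=int) > 0).astype(int)
    cm = confusion(yt, yp, 2)
    probs = None
    if positive_scores is not None:
        s = np.asarray(positive_scores, dtype=float)
        probs = np.stack([1.0 - s, s], axis=1)
    return weighted_metrics(cm, probabilities=probs, y_true=yt)


def summarize_folds(reports: Sequence[MetricsReport]) -> Dict[str, Dict[str, float]]:
    """Mean and standard deviation (as a percentage) of each metric across folds."""
    out: Dict[str, Dict[str, float]] = {}
    for name in ("acc", "sen", "spe", "f1", "auc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            continue
        out[name] = {
            "mean": float(np.mean(vals)),
            "sd_pct": float(np.std(vals) * 100.0),
        }
    return out
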