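"""Presence/absence model evaluation on held-out sites.

Discrimination is summarized by the ROC curve and its area (AUC,
computed as the Mann–Whitney probability that a random presence
outscores a random absence, ties counting one half). The operating
threshold follows the sensitivity = specificity rule; the resulting
confusion matrix yields sensitivity, specificity, the true skill
statistic TSS = sensitivity + specificity − 1, and Cohen's kappa from
the standard unweighted 2×2 formula.

Classification convention throughout: score ≥ threshold ⇒ predicted
presence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "threshold_sens_eq_spec",
    "confusion_and_metrics",
    "evaluate",
]


@dataclass
class EvaluationReport:
    roc: pd.DataFrame  # threshold, sensitivity, one_minus_specificity
    auc: float
    threshold: float
    threshold_rule: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    tss: float
    kappa: float

    def to_json(self) -> str:
        d = {
            k: getattr(self, k)
            for k in (
                "auc", "threshold", "threshold_rule", "tp", "fp", "fn",
                "tn", "sensitivity", "specificity", "tss", "kappa",
            )
        }
        return json.dumps(d, indent=2)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if s.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return s, y


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("both presence and absence labels are required")


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct score and the Mann–Whitney AUC."""
    s, y = _check_scores_labels(scores, labels)
    _require_both_classes(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # average ranks give ties half credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(s)[::-1]
    rows = [{"threshold": np.inf, "sensitivity": 0.0, "one_minus_specificity": 0.0}]
    for t in thresholds:
        pred = s >= t
        rows.append(
            {
                "threshold": float(t),
                "sensitivity": float((pred & (y == 1)).sum() / n_pos),
                "one_minus_specificity": float((pred & (y == 0)).sum() / n_neg),
            }
        )
    return pd.DataFrame(rows), float(auc)


def _sens_spec(s: np.ndarray, y: np.ndarray, t: float) -> tuple[float, float]:
    pred = s >= t
    sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
    spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
    return float(sens), float(spec)


def threshold_sens_eq_spec(scores, labels) -> float:
    """Threshold where sensitivity comes closest to specificity.

    Candidates are all distinct scores plus midpoints between adjacent
    distinct scores; among minimizers of |sens − spec| the smallest
    threshold wins.
    """
    s, y = _check_scores_labels(scores, labels)
    _require_both_classes(y)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.sort(np.concatenate([distinct, mids]))
    best_t, best_gap = None, np.inf
    for t in candidates:
        sens, spec = _sens_spec(s, y, float(t))
        gap = abs(sens - spec)
        if gap < best_gap - 1e-15:
            best_gap, best_t = gap, float(t)
    return best_t


def confusion_and_metrics(scores, labels, threshold: float,
                          threshold_rule: str = "fixed") -> EvaluationReport:
    """Confusion matrix and skill statistics at a given threshold."""
    s, y = _check_scores_labels(scores, labels)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return _report_from_counts(s, y, tp, fp, fn, tn, threshold, threshold_rule)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Sensitivity, specificity, TSS and kappa from 2×2 counts."""
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (fp + tn) if fp + tn else np.nan
    tss = sens + spec - 1.0
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "tss": float(tss),
        "kappa": float(kappa),
    }


def _report_from_counts(s, y, tp, fp, fn, tn, threshold, rule) -> EvaluationReport:
    m = metrics_from_counts(tp, fp, fn, tn)
    try:
        roc, auc = roc_auc(s, y)
    except ValueError:
        roc, auc = pd.DataFrame(), np.nan
    return EvaluationReport(
        roc=roc,
        auc=auc,
        threshold=float(threshold),
        threshold_rule=rule,
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        tss=m["tss"],
        kappa=m["kappa"],
    )


def evaluate(scores, labels, threshold: float | None = None) -> EvaluationReport:
    """Full evaluation; threshold defaults to the sens = spec rule."""
    if threshold is None:
        t = threshold_sens_eq_spec(scores, labels)
        return confusion_and_metrics(scores, labels, t, "sens=spec")
    return confusion_and_metrics(scores, labels, threshold, "fixed")
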