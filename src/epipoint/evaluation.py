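"""Classification metrics and validation-set threshold optimization.

MCC is the primary metric (robust under the heavy class imbalance of
epitope labelling); AUC, precision, recall and F1 are reported alongside.
All threshold-dependent metrics use a probability threshold chosen to
maximize MCC on a validation set. Metrics are pooled over residues across
complexes; per-complex rows are also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["confusion_metrics", "auc_score", "optimize_threshold",
           "MetricReport", "build_report"]


def confusion_metrics(calls: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, float, float, float]:
    """(MCC, precision, recall, F1) from binary calls vs labels.

    Any zero denominator (single-class labels or calls) yields 0 for the
    affected metric, the usual convention for degenerate confusion matrices.
    """
    calls = np.asarray(calls).astype(np.int64)
    labels = np.asarray(labels).astype(np.int64)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    tp = int(np.sum((calls == 1) & (labels == 1)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return float(mcc), float(precision), float(recall), float(f1)


def auc_score(probabilities: np.ndarray, labels: np.ndarray) -> float | None:
    """Rank-based (Mann-Whitney) ROC AUC with tie averaging; ``None`` when
    only one class is present (AUC undefined)."""
    labels = np.asarray(labels).astype(np.int64)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(probabilities, dtype=np.float64)))


def optimize_threshold(val_predictions: np.ndarray,
                       val_labels: np.ndarray) -> float:
    """Threshold maximizing pooled MCC over the validation set.

    The grid is the set of unique predicted probabilities plus {0, 1}
    (exact optimum for finite data); ties return the smallest threshold.
    """
    probs = np.asarray(val_predictions, dtype=np.float64)
    labels = np.asarray(val_labels).astype(np.int64)
    if probs.size == 0:
        raise ValueError("empty validation set")
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels must contain both classes")
    candidates = np.unique(np.concatenate([probs, [0.0, 1.0]]))
    best_t, best_mcc = candidates[0], -np.inf
    for t in candidates:
        mcc, _, _, _ = confusion_metrics((probs >= t).astype(np.int64), labels)
        if mcc > best_mcc + 1e-15:
            best_t, best_mcc = t, mcc
    return float(best_t)


@dataclass
class MetricReport:
    mcc: float
    auc: float | None
    precision: float
    recall: float
    f1: float
    threshold: float
    aggregation: str = "pooled"
    per_complex: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"mcc": self.mcc, "auc": self.auc, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "threshold": self.threshold, "aggregation": self.aggregation,
                "per_complex": self.per_complex}


def build_report(prob_sets: Sequence[np.ndarray],
                 label_sets: Sequence[np.ndarray],
                 threshold: float,
                 complex_ids: Sequence[str] | None = None) -> MetricReport:
    """Pooled metrics over residues of all complexes, plus per-complex rows."""
    if len(prob_sets) != len(label_sets):
        raise ValueError("need one label vector per prediction vector")
    ids = complex_ids or [f"complex_{i}" for i in range(len(prob_sets))]
    per_complex = []
    for cid, probs, labels in zip(ids, prob_sets, label_sets):
        calls = (np.asarray(probs) >= threshold).astype(np.int64)
        mcc, prec, rec, f1 = confusion_metrics(calls, labels)
        per_complex.append({"complex_id": cid, "mcc": mcc, "precision": prec,
                            "recall": rec, "f1": f1,
                            "auc": auc_score(probs, labels),
                            "n_residues": int(len(labels))})
    probs = np.concatenate([np.asarray(p, dtype=np.float64) for p in prob_sets])
    labels = np.concatenate([np.asarray(l).astype(np.int64) for l in label_sets])
    calls = (probs >= threshold).astype(np.int64)
    mcc, prec, rec, f1 = confusion_metrics(calls, labels)
    return MetricReport(mcc=mcc, auc=auc_score(probs, labels), precision=prec,
                        recall=rec, f1=f1, threshold=float(threshold),
                        per_complex=per_complex)
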