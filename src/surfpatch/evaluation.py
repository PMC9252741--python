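"""Evaluation metrics: per-protein ROC AUC, confusion metrics, accuracies.

ROC AUC uses the Mann-Whitney formulation (probability that a random positive
outranks a random negative, ties counted one half).  Binary confusion metrics
(MCC, F1, sensitivity, specificity) are computed at a configurable score
threshold, default 0.5.  Multi-class results are summarised by balanced
accuracy (mean per-class recall over classes present in the truth) and a
per-class accuracy table.  Standard metric computations delegate to
scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "EvalReport",
    "roc_auc",
    "confusion_metrics",
    "aggregate",
    "balanced_accuracy",
    "per_class_accuracy",
]


def roc_auc(scores, labels):
    """Mann-Whitney ROC AUC; ``None`` when only one class is present."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or (~labels).all():
        return None
    return float(_skm.roc_auc_score(labels, scores))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """MCC, F1, sensitivity and specificity at a score threshold.

    Zero-denominator MCC is reported as 0 (the conventional value for a
    degenerate confusion table).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    mcc = _skm.matthews_corrcoef(labels, pred)
    f1 = _skm.f1_score(labels, pred, zero_division=0.0)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "mcc": float(mcc), "f1": float(f1),
        "sensitivity": float(sens), "specificity": float(spec),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def aggregate(values, mode: str = "mean") -> float:
    """Mean or median over per-protein metric values (Nones dropped)."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("no values to aggregate")
    if mode == "mean":
        return float(np.mean(vals))
    if mode == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def balanced_accuracy(pred_classes, true_classes) -> float:
    """Mean per-class recall over the classes present in the truth."""
    true = np.asarray(true_classes)
    pred = np.asarray(pred_classes)
    if len(true) == 0:
        raise ValueError("empty truth")
    return float(_skm.balanced_accuracy_score(true, pred))


def per_class_accuracy(pred_classes, true_classes, classes=None) -> dict:
    """Recall per class; classes absent from the truth map to ``None``."""
    true = np.asarray(true_classes)
    pred = np.asarray(pred_classes)
    if classes is None:
        classes = sorted(set(true))
    out = {}
    for c in classes:
        sel = true == c
        out[c] = float(np.mean(pred[sel] == c)) if sel.any() else None
    return out


@dataclass
class EvalReport:
    """Collected evaluation results for one experiment."""

    per_protein_auc: list = field(default_factory=list)
    confusion: dict = field(default_factory=dict)
    balanced_acc: float | None = None
    class_accuracy: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return aggregate(self.per_protein_auc, "mean")

    @property
    def median_auc(self) -> float:
        return aggregate(self.per_protein_auc, "median")

    def as_dict(self) -> dict:
        out = {
            "per_protein_auc": [
                None if a is None else float(a) for a in self.per_protein_auc
            ],
        }
        if self.per_protein_auc:
            out["mean_auc"] = self.mean_auc
            out["median_auc"] = self.median_auc
        if self.confusion:
            out["confusion"] = self.confusion
        if self.balanced_acc is not None:
            out["balanced_accuracy"] = self.balanced_acc
        if self.class_accuracy:
            out["class_accuracy"] = self.class_accuracy
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        rows = []
        for i, a in enumerate(self.per_protein_auc):
            rows.append({"metric": f"auc_protein_{i}", "value": a})
        if self.per_protein_auc:
            rows.append({"metric": "mean_auc", "value": self.mean_auc})
            rows.append({"metric": "median_auc", "value": self.median_auc})
        for k, v in self.confusion.items():
            rows.append({"metric": k, "value": v})
        if self.balanced_acc is not None:
            rows.append({"metric": "balanced_accuracy",
                         "value": self.balanced_acc})
        for k, v in self.class_accuracy.items():
            rows.append({"metric": f"accuracy_{k}", "value": v})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
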