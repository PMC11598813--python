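"""Confusion-matrix metrics for the five AAMI beat classes.

The matrix orientation is rows = predicted class, columns = original class,
in the order N, S, V, F, Q.  Per class, with TP the diagonal entry, FP the
rest of its row, FN the rest of its column and TN everything else:

    Sen  = TP/(TP+FN)          Ppv = TP/(TP+FP)       Spec = TN/(TN+FP)
    two-class Acc = (TP+TN)/total          F1 = 2TP/(2TP+FP+FN)

Overall: five-class Acc = trace/total, macro-F1 = unweighted mean of the
five per-class F1 scores.  Zero-denominator metrics are reported as NaN
with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CLASS_ORDER = ("N", "S", "V", "F", "Q")

__all__ = ["CLASS_ORDER", "ConfusionMatrix5", "per_class_counts",
           "metric_report", "confusion_from_labels"]


@dataclass(frozen=True)
class ConfusionMatrix5:
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (5, 5) or np.any(c < 0):
            raise ValueError("confusion matrix must be 5x5 with nonnegative counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_labels(predicted, original) -> ConfusionMatrix5:
    """Aggregate per-sample class indices into a 5x5 matrix."""
    predicted = np.asarray(predicted, dtype=np.int64)
    original = np.asarray(original, dtype=np.int64)
    if predicted.shape != original.shape:
        raise ValueError("label lists must have equal length")
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (predicted, original), 1)
    return ConfusionMatrix5(counts)


def per_class_counts(cm: ConfusionMatrix5, cls: int | str):
    """(TP, TN, FP, FN) for one class of the 5x5 matrix."""
    i = CLASS_ORDER.index(cls) if isinstance(cls, str) else int(cls)
    c = cm.counts
    tp = int(c[i, i])
    fp = int(c[i].sum()) - tp
    fn = int(c[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, tn, fp, fn


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reported as NaN")
        return float("nan")
    return num / den


def round2(x: float) -> float:
    """Percentage display rounding: 2 decimals, round-half-even."""
    return float(np.round(x, 2))


def metric_report(cm: ConfusionMatrix5) -> dict:
    """Per-class and overall metrics, as raw ratios and display percentages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    f1s = []
    for i, name in enumerate(CLASS_ORDER):
        tp, tn, fp, fn = per_class_counts(cm, i)
        sen = _ratio(tp, tp + fn, f"Sen[{name}]")
        ppv = _ratio(tp, tp + fp, f"Ppv[{name}]")
        spec = _ratio(tn, tn + fp, f"Spec[{name}]")
        acc2 = (tp + tn) / cm.total
        f1 = _ratio(2 * tp, 2 * tp + fp + fn, f"F1[{name}]")
        f1s.append(f1)
        per_class[name] = {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "Sen": sen, "Ppv": ppv, "Spec": spec,
            "two_class_Acc": acc2, "F1": f1,
            "Sen_pct": round2(sen * 100), "Ppv_pct": round2(ppv * 100),
            "Spec_pct": round2(spec * 100),
            "two_class_Acc_pct": round2(acc2 * 100),
            "F1_pct": round2(f1 * 100),
        }
    acc5 = np.trace(cm.counts) / cm.total
    macro_f1 = float(np.mean(f1s))
    return {
        "per_class": per_class,
        "five_class_Acc": acc5,
        "macro_F1": macro_f1,
        "five_class_Acc_pct": round2(acc5 * 100),
        "macro_F1_pct": round2(macro_f1 * 100),
        "total": cm.total,
    }
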