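"""Per-class and overall evaluation of five-class beat predictions.

For each AAMI class the one-vs-rest counts give sensitivity
Se = TP/(TP+FN)*100, precision +P = TP/(TP+FP)*100 and
F1 = 2*TP/(2*TP+FP+FN)*100.  The headline accuracy is the overall
multiclass accuracy 100*trace/total; the one-vs-rest accuracy
(TP+TN)/total per class is also reported, macro-averaged, since per-class
accuracies of a one-vs-rest reduction are a common alternative convention.
Metrics of a class with zero relevant denominator are reported as NaN and
excluded from macro means, never coerced to 0 or 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import CLASS_ORDER

__all__ = ["ConfusionMatrix", "EvaluationReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts; rows = true class, columns = predicted, order (N,S,V,F,Q)."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-class Se/+P/F1 and support, overall and macro summaries (%)."""

    class_order: tuple[str, ...]
    se: dict[str, float]
    plus_p: dict[str, float]
    f1: dict[str, float]
    acc_ovr: dict[str, float]
    support: dict[str, int]
    acc: float
    macro_se: float
    macro_plus_p: float
    macro_f1: float
    macro_acc_ovr: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(d):
            return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in d.items()}

        return {
            "class_order": list(self.class_order),
            "se": clean(self.se),
            "plus_p": clean(self.plus_p),
            "f1": clean(self.f1),
            "acc_ovr": clean(self.acc_ovr),
            "support": self.support,
            "acc": self.acc,
            "macro_se": self.macro_se,
            "macro_plus_p": self.macro_plus_p,
            "macro_f1": self.macro_f1,
            "macro_acc_ovr": self.macro_acc_ovr,
            "undefined": self.undefined,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def format_table(self) -> str:
        lines = [
            f"overall Acc = {self.acc:.2f}%   "
            f"(macro one-vs-rest Acc = {self.macro_acc_ovr:.2f}%)",
            f"{'class':>5} {'n':>7} {'Se%':>8} {'+P%':>8} {'F1%':>8}",
        ]
        for c in self.class_order:
            fmt = lambda v: "   --" if math.isnan(v) else f"{v:8.2f}"
            lines.append(
                f"{c:>5} {self.support[c]:>7d} {fmt(self.se[c])} "
                f"{fmt(self.plus_p[c])} {fmt(self.f1[c])}"
            )
        lines.append(
            f"macro        {self.macro_se:8.2f} {self.macro_plus_p:8.2f} "
            f"{self.macro_f1:8.2f}"
        )
        if self.undefined:
            lines.append(f"undefined (zero support): {', '.join(self.undefined)}")
        return "\n".join(lines)


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into the fixed-order 5x5 matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    bad = set(true_labels) | set(predicted_labels)
    bad -= set(CLASS_ORDER)
    if bad:
        raise ValueError(f"labels outside the AAMI classes: {sorted(bad)}")
    if not true_labels:
        return ConfusionMatrix(np.zeros((5, 5), dtype=int))
    counts = _sk_confusion(
        true_labels, predicted_labels, labels=list(CLASS_ORDER)
    )
    return ConfusionMatrix(counts)


def _pct(num: float, den: float) -> float:
    return num / den * 100 if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Per-class one-vs-rest Se/+P/F1, overall and macro summaries."""
    if cm.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    c = cm.counts
    total = cm.total
    se, plus_p, f1, acc_ovr, support = {}, {}, {}, {}, {}
    undefined = []
    for i, cls in enumerate(cm.class_order):
        tp = int(c[i, i])
        fn = int(c[i].sum()) - tp
        fp = int(c[:, i].sum()) - tp
        tn = total - tp - fn - fp
        support[cls] = tp + fn
        se[cls] = _pct(tp, tp + fn)
        plus_p[cls] = _pct(tp, tp + fp)
        f1[cls] = _pct(2 * tp, 2 * tp + fp + fn)
        acc_ovr[cls] = _pct(tp + tn, total)
        if any(math.isnan(v) for v in (se[cls], plus_p[cls], f1[cls])):
            undefined.append(cls)

    def macro(d: dict[str, float]) -> float:
        vals = [v for v in d.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return EvaluationReport(
        class_order=cm.class_order,
        se=se,
        plus_p=plus_p,
        f1=f1,
        acc_ovr=acc_ovr,
        support=support,
        acc=float(np.trace(c)) / total * 100,
        macro_se=macro(se),
        macro_plus_p=macro(plus_p),
        macro_f1=macro(f1),
        macro_acc_ovr=macro(acc_ovr),
        undefined=undefined,
    )


def evaluate(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> EvaluationReport:
    """Convenience wrapper: confusion + metrics in one call."""
    return metrics(confusion(true_labels, predicted_labels))
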