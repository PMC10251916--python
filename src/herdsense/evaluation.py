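"""Confusion matrices and multi-class performance metrics.

Implements the standard contingency bookkeeping for the five behaviour
classes: per-class true/false positives and negatives, precision
TP/(TP+FP), recall TP/(TP+FN), F1 = 2pr/(p+r), overall accuracy
trace/total, and macro (unweighted) plus support-weighted averages —
the weighted form being the informative one under the strong class
imbalance typical of these recordings (resting dominates).

Axis convention: confusion-matrix **rows are actual classes, columns
are predicted**, in the fixed order (feeding, moving, resting,
ruminating, standing_still), so row sums equal per-class supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import CLASSES


@dataclass
class ClassMetrics:
    """Per-class tallies and derived scores."""

    label: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    support: int
    undefined: tuple[str, ...] = ()  # metrics hit a 0/0 and were set to 0


@dataclass
class EvalReport:
    """Confusion matrix plus every derived metric."""

    matrix: pd.DataFrame = field(repr=False)   # rows actual, cols predicted
    per_class: list[ClassMetrics]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    total: int


def confusion(actual, predicted, classes: tuple = CLASSES) -> pd.DataFrame:
    """Tally actual-vs-predicted counts into a labelled matrix.

    Entry (i, j) counts units of actual class i predicted as class j.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError(f"length mismatch: {len(actual)} actual vs "
                         f"{len(predicted)} predicted")
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted({*actual, *predicted} - set(classes))
    if unknown:
        raise ValueError(f"labels outside the vocabulary: {unknown}")
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        m[index[a], index[p]] += 1
    return pd.DataFrame(m, index=list(classes), columns=list(classes))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(matrix: pd.DataFrame) -> EvalReport:
    """Derive the full metric report from a confusion matrix.

    A class absent from both the actual and predicted streams has
    undefined precision/recall; those are reported as 0 and flagged in
    ``ClassMetrics.undefined`` rather than raising.
    """
    m = matrix.to_numpy(dtype=np.int64)
    total = int(m.sum())
    if total <= 0:
        raise ValueError("empty confusion matrix")
    classes = list(matrix.index)
    per_class: list[ClassMetrics] = []
    for i, label in enumerate(classes):
        tp = int(m[i, i])
        fn = int(m[i].sum() - tp)
        fp = int(m[:, i].sum() - tp)
        tn = total - tp - fn - fp
        undef = []
        precision, u = _safe_div(tp, tp + fp)
        if u:
            undef.append("precision")
        recall, u = _safe_div(tp, tp + fn)
        if u:
            undef.append("recall")
        f1, u = _safe_div(2 * precision * recall, precision + recall)
        if u:
            undef.append("f1")
        per_class.append(ClassMetrics(
            label=label, tp=tp, fp=fp, fn=fn, tn=tn,
            precision=precision, recall=recall, f1=f1,
            support=tp + fn, undefined=tuple(undef)))

    supports = np.array([c.support for c in per_class], dtype=float)
    weights = supports / supports.sum()
    prec = np.array([c.precision for c in per_class])
    rec = np.array([c.recall for c in per_class])
    f1s = np.array([c.f1 for c in per_class])
    return EvalReport(
        matrix=matrix.copy(),
        per_class=per_class,
        accuracy=float(np.trace(m)) / total,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1s.mean()),
        weighted_precision=float(prec @ weights),
        weighted_recall=float(rec @ weights),
        weighted_f1=float(f1s @ weights),
        total=total)


def round2(x: float) -> float:
    """Round half up to 2 decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def report_to_dict(report: EvalReport) -> dict:
    """Full-precision machine-readable form of a report."""
    return {
        "classes": list(report.matrix.index),
        "confusion_matrix": report.matrix.to_numpy().tolist(),
        "per_class": {
            c.label: {
                "precision": c.precision, "recall": c.recall, "f1": c.f1,
                "support": c.support, "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "tn": c.tn, "undefined": list(c.undefined),
            } for c in report.per_class},
        "accuracy": report.accuracy,
        "macro": {"precision": report.macro_precision,
                  "recall": report.macro_recall, "f1": report.macro_f1},
        "weighted": {"precision": report.weighted_precision,
                     "recall": report.weighted_recall,
                     "f1": report.weighted_f1},
        "total": report.total,
    }


def report_render(report: EvalReport) -> tuple[str, str]:
    """Human-readable table plus machine-readable JSON.

    The text table rounds half-up to two decimals; the JSON keeps full
    precision.  Classes with undefined (0/0) metrics are marked ``*``.
    """
    rows = []
    for c in report.per_class:
        star = "*" if c.undefined else ""
        rows.append(f"{c.label:<16}{round2(c.precision):>10.2f}"
                    f"{round2(c.recall):>10.2f}{round2(c.f1):>10.2f}"
                    f"{c.support:>10}{star}")
    text = "\n".join([
        f"{'Behaviour':<16}{'Precision':>10}{'Recall':>10}{'F1':>10}"
        f"{'Units':>10}",
        "-" * 56,
        *rows,
        "-" * 56,
        f"{'Accuracy':<16}{'':>10}{'':>10}"
        f"{round2(report.accuracy):>10.2f}{report.total:>10}",
        f"{'Macro avg':<16}{round2(report.macro_precision):>10.2f}"
        f"{round2(report.macro_recall):>10.2f}"
        f"{round2(report.macro_f1):>10.2f}{report.total:>10}",
        f"{'Weighted avg':<16}{round2(report.weighted_precision):>10.2f}"
        f"{round2(report.weighted_recall):>10.2f}"
        f"{round2(report.weighted_f1):>10.2f}{report.total:>10}",
    ])
    return text, json.dumps(report_to_dict(report), indent=2)


def matrix_to_csv(report: EvalReport, path) -> None:
    """Write the labelled confusion matrix (rows actual)."""
    report.matrix.rename_axis("actual\\predicted").to_csv(path)
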