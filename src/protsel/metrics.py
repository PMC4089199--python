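"""Multiclass evaluation panel from a confusion matrix.

Rows are actual classes, columns predicted. Per-class metrics use the
one-vs-rest reduction (TP on the diagonal, FN along the row, FP down the
column, TN everywhere else); the panel covers accuracy, TPR, FPR,
sensitivity, specificity, precision, recall, F-measure and Matthews
correlation coefficient. Both unweighted macro averages and
support-weighted averages are reported. Any 0/0 cell is defined as 0 and
flagged rather than raising, so degenerate runs still aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DatasetError, ShapeError

PER_CLASS_METRICS = (
    "TPR",
    "FPR",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "F-measure",
    "MCC",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # (C, C) non-negative integers, rows = actual

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ShapeError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] != len(self.classes):
            raise ShapeError("class list does not match matrix dimension")
        if (counts < 0).any():
            raise DatasetError("confusion matrix has negative counts")
        if counts.sum() < 1:
            raise DatasetError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EvaluationReport:
    classes: tuple[str, ...]
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    weighted: dict[str, float]
    undefined: tuple[tuple[str, str], ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
            "weighted": self.weighted,
            "undefined": [list(u) for u in self.undefined],
        }


def confusion_from_predictions(
    actual, predicted, classes: list[str] | tuple[str, ...]
) -> ConfusionMatrix:
    """Count a C x C confusion matrix from aligned label vectors."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ShapeError(f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
    if not actual:
        raise DatasetError("empty prediction vectors")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in idx:
            raise DatasetError(f"unknown actual label {a!r}")
        if p not in idx:
            raise DatasetError(f"unknown predicted label {p!r}")
        counts[idx[a], idx[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def _safe_div(num: float, den: float, flags: list, cls: str, name: str) -> float:
    if den == 0:
        if num != 0:  # cannot happen for the ratios used here, kept defensive
            raise ZeroDivisionError(f"{name} for {cls}: {num}/0")
        flags.append((cls, name))
        return 0.0
    return num / den


def compute_report(cm: ConfusionMatrix) -> EvaluationReport:
    """One-vs-rest metric panel plus macro and support-weighted averages."""
    counts = np.asarray(cm.counts, dtype=np.float64)
    total = counts.sum()
    accuracy = float(np.trace(counts) / total)
    per_class: dict[str, dict[str, float]] = {}
    flags: list[tuple[str, str]] = []
    supports = counts.sum(axis=1)
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = _safe_div(tp, tp + fn, flags, c, "sensitivity")
        spec = _safe_div(tn, tn + fp, flags, c, "specificity")
        fpr = _safe_div(fp, fp + tn, flags, c, "FPR")
        prec = _safe_div(tp, tp + fp, flags, c, "precision")
        f1 = _safe_div(2 * prec * sens, prec + sens, flags, c, "F-measure")
        mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if mcc_den == 0:
            flags.append((c, "MCC"))
            mcc = 0.0
        else:
            mcc = (tp * tn - fp * fn) / mcc_den
        per_class[c] = {
            "TPR": sens,
            "FPR": fpr,
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "recall": sens,
            "F-measure": f1,
            "MCC": mcc,
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes]))
        for m in PER_CLASS_METRICS
    }
    weights = supports / total
    weighted = {
        m: float(sum(w * per_class[c][m] for w, c in zip(weights, cm.classes)))
        for m in PER_CLASS_METRICS
    }
    return EvaluationReport(
        classes=cm.classes,
        accuracy=accuracy,
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        undefined=tuple(flags),
    )


def write_confusion_tsv(cm: ConfusionMatrix, path: str | Path) -> None:
    """TSV dialect mirroring the printed tables: header row of predicted
    labels, first column actual labels, integer cells."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("actual\\predicted\t" + "\t".join(cm.classes) + "\n")
        for i, c in enumerate(cm.classes):
            fh.write(c + "\t" + "\t".join(str(int(x)) for x in cm.counts[i]) + "\n")


def read_confusion_tsv(path: str | Path) -> ConfusionMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise DatasetError(f"confusion TSV {path} has no data rows")
    classes = tuple(lines[0].split("\t")[1:])
    rows = []
    row_labels = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        row_labels.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    if tuple(row_labels) != classes:
        raise DatasetError(
            f"confusion TSV {path}: row labels {row_labels} do not match header {list(classes)}"
        )
    return ConfusionMatrix(classes, np.asarray(rows, dtype=np.int64))
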