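"""Confusion matrices and multiclass performance metrics.

The confusion matrix is oriented rows = predicted, columns = actual.
Per-class sensitivity (recall) is diagonal / column sum and per-class
precision is diagonal / row sum.  Macro averages weight every class
equally; micro averages aggregate TP/FP/FN counts over classes first.
For single-label multiclass data, micro sensitivity, micro precision and
accuracy all equal trace / total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .classifier import LabelMap
from .errors import InvalidInputError


@dataclass(frozen=True)
class ConfusionMatrix:
    """J x J counts; ``counts[p, a]`` = samples predicted as class p+1
    with actual class a+1 (classes in label order)."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InvalidInputError("counts must be a square matrix")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        if len(self.labels) != counts.shape[0]:
            raise InvalidInputError("label count must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Printable layout: rows = predicted, columns = actual."""
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class MetricsReport:
    """All classification metrics in macro (M) and micro (mu) forms."""

    accuracy: float
    per_class_sensitivity: tuple[float, ...]
    per_class_precision: tuple[float, ...]
    sensitivity_macro: float
    precision_macro: float
    f1_macro: float
    sensitivity_micro: float
    precision_micro: float
    f1_micro: float
    zero_denominator_classes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_series(self) -> pd.Series:
        d = self.to_dict()
        d.pop("per_class_sensitivity")
        d.pop("per_class_precision")
        d.pop("zero_denominator_classes")
        return pd.Series(d)


def confusion_matrix(true_labels, predicted_labels, label_map: LabelMap) -> ConfusionMatrix:
    """Tally a rows-predicted / columns-actual confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise InvalidInputError("true and predicted label sequences differ in length")
    j = label_map.n_classes
    t = label_map.encode(true_labels) - 1
    p = label_map.encode(predicted_labels) - 1
    counts = np.zeros((j, j), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    return ConfusionMatrix(counts, label_map.ordered_labels)


def f1_from(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2PS/(P+S); 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise InvalidInputError("precision and sensitivity must be in [0, 1]")
    denom = precision + sensitivity
    if denom == 0.0:
        return 0.0
    return 2.0 * precision * sensitivity / denom


def classification_report(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy and macro/micro sensitivity, precision and F1.

    Classes with a zero row or column sum contribute 0 to the macro means
    and are flagged in ``zero_denominator_classes``.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise InvalidInputError("empty confusion matrix")
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)  # actual-class totals
    row = counts.sum(axis=1).astype(float)  # predicted-class totals

    flagged = tuple(int(i) for i in np.flatnonzero((col == 0) | (row == 0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(col > 0, diag / np.where(col > 0, col, 1.0), 0.0)
        prec = np.where(row > 0, diag / np.where(row > 0, row, 1.0), 0.0)

    accuracy = float(diag.sum() / total)
    sens_m = float(sens.mean())
    prec_m = float(prec.mean())
    # micro: aggregate TP / FP / FN over classes
    tp = diag.sum()
    fn = (col - diag).sum()
    fp = (row - diag).sum()
    sens_mu = float(tp / (tp + fn))
    prec_mu = float(tp / (tp + fp))
    return MetricsReport(
        accuracy=accuracy,
        per_class_sensitivity=tuple(float(s) for s in sens),
        per_class_precision=tuple(float(p) for p in prec),
        sensitivity_macro=sens_m,
        precision_macro=prec_m,
        f1_macro=f1_from(prec_m, sens_m),
        sensitivity_micro=sens_mu,
        precision_micro=prec_mu,
        f1_micro=f1_from(prec_mu, sens_mu),
        zero_denominator_classes=flagged,
    )


def summarize_scores(values) -> tuple[float, float]:
    """Mean and population (divide-by-n) standard deviation of a set of
    per-dataset scores — the convention used when aggregating a
    classifier's performance across experiments."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("no scores to summarize")
    return float(arr.mean()), float(arr.std(ddof=0))
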