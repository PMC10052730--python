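"""Diagnostic performance metrics from one-vs-rest confusion counts.

Two formula conventions are provided:

``canonical``
    The standard definitions: specificity = TN/(TN+FP), disease
    prevalence = (TP+FN)/total, NPV = TN/(TN+FN).

``as_printed``
    A literal variant in which specificity divides TN by (TN+FN),
    prevalence duplicates the accuracy ratio (TP+TN)/total, and NPV
    divides TN by (TN+FP).  It is kept so results computed under either
    reading can be reproduced and compared; ``canonical`` is the
    default.

Sensitivity, accuracy and precision (= PPV) agree between the two
conventions.  A ratio with a zero denominator is reported as ``None``
(undefined), never silently as 0.  Multiclass aggregation is macro
(unweighted) over one-vs-rest reports.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "binary_metrics",
    "macro_report",
    "CONVENTIONS",
]

CONVENTIONS = ("canonical", "as_printed")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tallies: true/false positives and negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped_roles(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricsReport:
    """Per-metric values in [0, 1]; ``None`` marks an undefined ratio."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    prevalence: float | None
    npv: float | None
    ppv: float | None
    convention: str = "canonical"

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> ConfusionCounts:
    """Tally one-vs-rest confusion counts for ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def binary_metrics(
    counts: ConfusionCounts, convention: str = "canonical"
) -> MetricsReport:
    """Compute the six diagnostic metrics from confusion counts."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sensitivity = _ratio(tp, tp + fn)
    accuracy = _ratio(tp + tn, counts.total)
    precision = _ratio(tp, tp + fp)
    if convention == "canonical":
        specificity = _ratio(tn, tn + fp)
        prevalence = _ratio(tp + fn, counts.total)
        npv = _ratio(tn, tn + fn)
    else:  # literal printed formulas
        specificity = _ratio(tn, tn + fn)
        prevalence = _ratio(tp + tn, counts.total)
        npv = _ratio(tn, tn + fp)
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        precision=precision,
        prevalence=prevalence,
        npv=npv,
        ppv=precision,
        convention=convention,
    )


_METRIC_FIELDS = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "prevalence",
    "npv",
    "ppv",
)


def macro_report(
    y_true: Sequence,
    y_pred: Sequence,
    classes: Iterable,
    convention: str = "canonical",
) -> dict:
    """One-vs-rest report per class plus the macro (unweighted) average.

    The macro value of a metric averages over the classes where it is
    defined; if it is undefined for every class the macro value is
    ``None``.  Returns ``{"per_class": {cls: MetricsReport}, "macro":
    MetricsReport}``.
    """
    classes = list(classes)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    observed = set(y_true) | set(y_pred)
    unknown = observed - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(map(str, unknown))}")

    per_class = {
        cls: binary_metrics(confusion_counts(y_true, y_pred, cls), convention)
        for cls in classes
    }
    macro_vals: dict[str, float | None] = {}
    for name in _METRIC_FIELDS:
        defined = [
            getattr(r, name) for r in per_class.values() if getattr(r, name) is not None
        ]
        macro_vals[name] = float(np.mean(defined)) if defined else None
    macro = MetricsReport(convention=convention, **macro_vals)
    return {"per_class": per_class, "macro": macro}
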