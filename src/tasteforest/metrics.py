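"""Evaluation metric panel for two-class taste prediction.

All threshold metrics derive from the confusion counts for a chosen
positive class; either class may play the positive role, so a full
evaluation is a *dual* report (one perspective per class).  Rates are
stored as fractions in [0, 1]; rendering to percent is left to the
presentation layer.  Undefined ratios (zero denominators) are reported
as NaN, never coerced to 0.

Definitions, for positive class P with counts (tp, tn, fp, fn) and
N = tp + tn + fp + fn:

- accuracy      = (tp + tn) / N
- sensitivity   = tp / (tp + fn)          (recall, true-positive rate)
- specificity   = tn / (tn + fp)          (true-negative rate)
- precision     = tp / (tp + fp)          (positive predictive value)
- F-measure     = 2 · precision · recall / (precision + recall)
- NER           = (sensitivity + specificity) / 2   (non-error rate,
  balanced accuracy)
- Cohen's kappa = (p_o − p_e) / (1 − p_e), with p_o the accuracy and
  p_e the chance agreement from the marginal products
- ROC-AUC       = P(score of a random positive > score of a random
  negative), ties counting 1/2 — the Mann–Whitney statistic normalized
  by n_pos · n_neg, identical to the trapezoidal area under the
  empirical ROC curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

CLASSES = ("sweet", "bitter")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN for one positive-class perspective."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The full metric panel for one positive-class perspective."""

    positive_class: str
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    ner: float
    cohens_kappa: float
    roc_auc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_row(self) -> dict:
        """Flat row in validation-table layout (percent accuracy/NER)."""
        c = self.counts
        return {
            "positive_class": self.positive_class,
            "positives": c.tp + c.fn,
            "negatives": c.tn + c.fp,
            "accuracy_pct": 100.0 * self.accuracy,
            "roc_auc": self.roc_auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ner_pct": 100.0 * self.ner,
            "cohens_kappa": self.cohens_kappa,
            "f_measure": self.f_measure,
        }


def _check_classes(values: Sequence[str]) -> None:
    unknown = set(values) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown class tokens {sorted(unknown)}; expected {CLASSES}")


def confusion(labels: Sequence[str], predictions: Sequence[str],
              positive_class: str) -> ConfusionCounts:
    """Count confusion cells for the given positive class."""
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs "
                         f"{len(predictions)} predictions")
    _check_classes(labels)
    _check_classes(predictions)
    _check_classes([positive_class])
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, positive_class=positive_class)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def panel(counts: ConfusionCounts, roc_auc_value: float = math.nan) -> MetricsReport:
    """Derive the full metric panel from confusion counts.

    ``roc_auc_value`` is filled in when scores are available (see
    :func:`evaluate`); the threshold metrics need only the counts.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion counts")
    accuracy = (tp + tn) / n
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f_measure = math.nan
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    ner = (sensitivity + specificity) / 2
    # chance agreement from the marginals
    p_pos_true = (tp + fn) / n
    p_pos_pred = (tp + fp) / n
    p_e = p_pos_true * p_pos_pred + (1 - p_pos_true) * (1 - p_pos_pred)
    kappa = _ratio(accuracy - p_e, 1 - p_e) if p_e < 1 else math.nan
    if p_e == 1:
        kappa = math.nan  # all-one-class marginals: agreement is vacuous
    return MetricsReport(
        positive_class=counts.positive_class, accuracy=accuracy,
        sensitivity=sensitivity, specificity=specificity, precision=precision,
        f_measure=f_measure, ner=ner, cohens_kappa=kappa,
        roc_auc=roc_auc_value, counts=counts)


def roc_auc(labels: Sequence[str], positive_scores: Sequence[float],
            positive_class: str) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) formula.

    Ties contribute 1/2 via midranks; the value equals the trapezoidal
    area under the empirical ROC curve.  A perfect ranking yields 1.0;
    constant scores yield 0.5.
    """
    if len(labels) != len(positive_scores):
        raise ValueError("labels and scores differ in length")
    _check_classes(labels)
    scores = np.asarray(positive_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = np.array([y == positive_class for y in labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs at least one positive and one negative label")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate(labels: Sequence[str], predictions: Sequence[str],
             positive_scores: Sequence[float], positive_class: str) -> MetricsReport:
    """Full report: confusion cells, threshold panel, and ROC-AUC.

    A dual report mirroring both class perspectives is obtained by
    calling once per class with that class's scores; sensitivity in one
    perspective equals specificity in the other.
    """
    counts = confusion(labels, predictions, positive_class)
    auc = roc_auc(labels, positive_scores, positive_class)
    return panel(counts, roc_auc_value=auc)


def dual_report(labels: Sequence[str], predictions: Sequence[str],
                sweet_scores: Sequence[float]) -> dict[str, MetricsReport]:
    """Evaluate from both class perspectives.

    ``sweet_scores`` are the scores of the sweet class; bitter scores
    are their complement (the two class scores of any prediction sum
    to 1).
    """
    sweet_scores = np.asarray(sweet_scores, dtype=float)
    return {
        "sweet": evaluate(labels, predictions, sweet_scores, "sweet"),
        "bitter": evaluate(labels, predictions, 1.0 - sweet_scores, "bitter"),
    }


def reports_to_csv(reports: Sequence[MetricsReport], path) -> None:
    """Export reports as a validation-style CSV table."""
    import pandas as pd

    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
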