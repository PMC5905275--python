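"""Applicability-domain assessment and confidence-thresholded screening.

A prediction is only as trustworthy as the query's resemblance to the
training chemistry.  The applicability domain (AD) here is defined by
the maximum Tanimoto similarity of a query's fingerprint to any
training-set fingerprint; queries below the cutoff are flagged as
out-of-domain but still predicted — AD is advisory, with confidence
thresholds (0.60 / 0.75 / 0.95) doing the noise filtering in batch
screens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .chem_io import MoleculeRecord
from .fingerprints import fingerprint_matrix
from .model import Prediction, TrainedModel, predict

#: default max-Tanimoto AD cutoff — a permissive community choice,
#: always echoed in the report
DEFAULT_AD_THRESHOLD = 0.25


@dataclass(frozen=True)
class ADReport:
    """Applicability-domain assessment of one query compound."""

    id: str
    max_similarity: float
    nearest_training_id: str
    in_domain: bool
    threshold: float


@dataclass(frozen=True)
class ScreenSummary:
    """Class counts of a library screen above one confidence cutoff.

    Fractions are computed over the full library size ``n_total``, not
    only over the retained compounds.
    """

    threshold: float
    n_total: int
    n_bitter_above: int
    n_sweet_above: int
    fraction_bitter: float
    fraction_sweet: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def ad_assess(model: TrainedModel, queries: Sequence[MoleculeRecord],
              threshold: float = DEFAULT_AD_THRESHOLD) -> list[ADReport]:
    """Max Tanimoto similarity of each query to the training set.

    Deterministic and invariant to training-set order: the nearest
    training id is the first-encountered row achieving the maximum.
    """
    if model.training_matrix is None or model.training_matrix.shape[0] == 0:
        raise ValueError("model retains no training fingerprints")
    if not queries:
        return []
    qx, qids = fingerprint_matrix(list(queries), model.config.fingerprint_kind)
    tx = model.training_matrix.astype(np.int64)
    train_counts = tx.sum(axis=1)
    out = []
    for qi, row in enumerate(qx.astype(np.int64)):
        inter = tx @ row
        union = train_counts + row.sum() - inter
        # both-empty pairs are identical all-zero fingerprints
        sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        best = int(np.argmax(sims))
        best_sim = float(sims[best])
        out.append(ADReport(id=qids[qi], max_similarity=best_sim,
                            nearest_training_id=model.training_ids[best],
                            in_domain=best_sim >= threshold, threshold=threshold))
    return out


def screen(model: TrainedModel, library: Sequence[MoleculeRecord],
           confidence_threshold: float) -> tuple[list[tuple[Prediction, bool]], ScreenSummary]:
    """Predict a compound library and summarize above a confidence cutoff.

    Every compound is predicted and emitted; those below the threshold
    carry a ``False`` above-threshold flag and are excluded from the
    summary counts.  Fractions are over the whole library.
    """
    if not 0.5 <= confidence_threshold <= 1.0:
        raise ValueError("confidence threshold must be in [0.5, 1]")
    preds = predict(model, library)
    flagged = [(p, p.confidence >= confidence_threshold) for p in preds]
    n_bitter = sum(1 for p, ok in flagged if ok and p.predicted_class == "bitter")
    n_sweet = sum(1 for p, ok in flagged if ok and p.predicted_class == "sweet")
    n_total = len(library)
    summary = ScreenSummary(
        threshold=confidence_threshold, n_total=n_total,
        n_bitter_above=n_bitter, n_sweet_above=n_sweet,
        fraction_bitter=n_bitter / n_total if n_total else 0.0,
        fraction_sweet=n_sweet / n_total if n_total else 0.0)
    return flagged, summary


def threshold_sweep(model: TrainedModel, library: Sequence[MoleculeRecord],
                    thresholds: Sequence[float] = (0.60, 0.75, 0.95)) -> list[ScreenSummary]:
    """Screen a library at several ascending confidence cutoffs.

    Retained counts are non-increasing in the threshold.  Predictions
    are computed once and re-thresholded.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    preds = predict(model, library)
    n_total = len(library)
    summaries = []
    for t in thresholds:
        if not 0.5 <= t <= 1.0:
            raise ValueError("confidence threshold must be in [0.5, 1]")
        n_bitter = sum(1 for p in preds
                       if p.confidence >= t and p.predicted_class == "bitter")
        n_sweet = sum(1 for p in preds
                      if p.confidence >= t and p.predicted_class == "sweet")
        summaries.append(ScreenSummary(
            threshold=t, n_total=n_total,
            n_bitter_above=n_bitter, n_sweet_above=n_sweet,
            fraction_bitter=n_bitter / n_total if n_total else 0.0,
            fraction_sweet=n_sweet / n_total if n_total else 0.0))
    return summaries


def screening_csv(model: TrainedModel, library: Sequence[MoleculeRecord],
                  confidence_threshold: float, path,
                  ad_threshold: float = DEFAULT_AD_THRESHOLD) -> ScreenSummary:
    """Full screening CSV: prediction, threshold flag, and AD columns."""
    import pandas as pd

    flagged, summary = screen(model, library, confidence_threshold)
    ad = {r.id: r for r in ad_assess(model, library, ad_threshold)}
    pd.DataFrame([{
        "id": p.id, "predicted_class": p.predicted_class,
        "confidence": p.confidence, "above_threshold": ok,
        "max_similarity": ad[p.id].max_similarity,
        "nearest_training_id": ad[p.id].nearest_training_id,
        "in_domain": ad[p.id].in_domain,
    } for p, ok in flagged]).to_csv(path, index=False)
    return summary
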