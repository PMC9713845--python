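"""Per-participant and macro-averaged evaluation of adherence predictions.

Five metrics are computed on each participant's 30 test days with the
adherent class as the positive class: precision TP/(TP+FP), recall
TP/(TP+FN), their harmonic mean F1, accuracy (TP+TN)/total, and the area
under the ROC curve. AUC uses the rank (Mann-Whitney) formulation -- the
probability that a random positive is scored above a random negative, ties
counted one half -- which equals trapezoidal integration of the ROC curve.

A metric can be undefined for a degenerate participant (no positive
predictions, single-class test labels); undefined values are reported as
such and excluded from the macro means, with exclusion counts surfaced in
the cohort report rather than silently imputed as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ParticipantMetrics",
    "CohortReport",
    "EvaluationError",
    "METRIC_NAMES",
    "confusion",
    "rank_auc",
    "metrics",
    "aggregate",
]

METRIC_NAMES = ("precision", "recall", "f1", "auc", "accuracy")


class EvaluationError(ValueError):
    """Invalid inputs to the evaluation routines."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with positive class = adherent (label 1)."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.size == 0:
        raise EvaluationError("labels must be non-empty")
    if y.shape != yhat.shape:
        raise EvaluationError(
            f"length mismatch: {y.shape} labels vs {yhat.shape} predictions"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
    )


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank statistic.

    Mean over positive-negative pairs of 1 (positive scored higher),
    1/2 (tie), 0 (lower). NaN when the labels are single-class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels must align")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        return math.nan
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


@dataclass(frozen=True)
class ParticipantMetrics:
    """The five metrics for one participant; NaN marks an undefined metric."""

    participant_id: str
    precision: float
    recall: float
    f1: float
    auc: float
    accuracy: float
    n_test: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics(
    counts: ConfusionCounts,
    scores: Sequence[float],
    labels: Sequence[int],
    participant_id: str = "",
) -> ParticipantMetrics:
    """Compute the five metrics from counts and ranking scores.

    Precision is undefined with no positive predictions, recall with no
    positive labels, F1 when either is undefined or both are zero, and AUC
    for single-class labels; undefined values are NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels must align")
    if counts.total != y.size:
        raise EvaluationError("confusion total does not match label count")
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else math.nan
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (counts.tp + counts.tn) / counts.total
    return ParticipantMetrics(
        participant_id=participant_id,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=rank_auc(s, y),
        accuracy=accuracy,
        n_test=counts.total,
    )


@dataclass(frozen=True)
class CohortReport:
    """Macro (per-participant, unweighted) means with exclusion bookkeeping."""

    per_participant: tuple[ParticipantMetrics, ...]
    macro: Mapping[str, float]
    n_contributing: Mapping[str, int]
    n_excluded: Mapping[str, int]


def aggregate(per_participant: Iterable[ParticipantMetrics]) -> CohortReport:
    """Unweighted mean of each metric over the participants where it is
    defined; the report records how many were excluded per metric."""
    pm = tuple(per_participant)
    if not pm:
        raise EvaluationError("cannot aggregate an empty collection")
    macro: dict[str, float] = {}
    n_contrib: dict[str, int] = {}
    n_excl: dict[str, int] = {}
    for name in METRIC_NAMES:
        values = np.array([getattr(p, name) for p in pm], dtype=float)
        defined = values[~np.isnan(values)]
        macro[name] = float(defined.mean()) if defined.size else math.nan
        n_contrib[name] = int(defined.size)
        n_excl[name] = len(pm) - int(defined.size)
    return CohortReport(
        per_participant=pm,
        macro=macro,
        n_contributing=n_contrib,
        n_excluded=n_excl,
    )
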