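"""Scoring inferred edge frequencies against a gold-standard topology.

Evaluation is unsigned and ignores self-regulation: the positives are the
off-diagonal entries of the gold standard with a nonzero (+ or -) sign, and
every off-diagonal gene pair is a candidate.  Curves are swept over the
distinct score values (stability scores take at most N + 1 values, so ties
are grouped at a single threshold step); areas are trapezoidal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .simulate import NetworkMatrix
from .stability import EdgeFrequencyMatrix

__all__ = [
    "GoldStandard",
    "CurveSet",
    "ConfusionSummary",
    "roc_pr_curves",
    "confusion_at_threshold",
]


@dataclass(frozen=True)
class GoldStandard:
    """Signed reference adjacency; signs are collapsed to presence/absence."""

    adjacency: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if not np.all(np.isin(adj, (-1, 0, 1))):
            raise ValueError("gold standard entries must be in {-1, 0, +1}")
        adj = adj.astype(int)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = adj.shape[0]
        if adj.ndim != 2 or adj.shape != (p, p) or len(self.gene_ids) != p:
            raise ValueError("gold standard must be square and match gene_ids")

    @classmethod
    def from_network(cls, network: NetworkMatrix) -> "GoldStandard":
        return cls(adjacency=network.signs, gene_ids=network.gene_ids)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class CurveSet:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    pr_thresholds: np.ndarray
    auroc: float
    aupr: float


@dataclass(frozen=True)
class ConfusionSummary:
    tpr: float
    fpr: float
    precision: float  # NaN when no edge is predicted
    precision_defined: bool
    n_predicted: int


def _flatten_off_diagonal(
    scores: EdgeFrequencyMatrix, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    if scores.gene_ids != gold.gene_ids:
        raise ValueError("score matrix and gold standard gene sets differ")
    p = gold.p
    mask = ~np.eye(p, dtype=bool)
    y_true = (gold.adjacency != 0)[mask]
    y_score = scores.scores[mask]
    if y_true.all() or not y_true.any():
        raise ValueError(
            "gold standard must contain at least one positive and one "
            "negative off-diagonal entry"
        )
    return y_true.astype(int), y_score


def roc_pr_curves(scores: EdgeFrequencyMatrix, gold: GoldStandard) -> CurveSet:
    """ROC and precision-recall curves with trapezoidal areas.

    The artificial recall-0 endpoint carries the precision of the
    highest-score group rather than an interpolated 1.0.
    """
    y_true, y_score = _flatten_off_diagonal(scores, gold)
    fpr, tpr, roc_thr = roc_curve(y_true, y_score, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, pr_thr = precision_recall_curve(y_true, y_score)
    if len(precision) > 1:
        precision = precision.copy()
        precision[-1] = precision[-2]  # recall-0 endpoint, highest-score group
    aupr = float(np.trapezoid(precision[::-1], recall[::-1]))
    return CurveSet(
        fpr=fpr, tpr=tpr, roc_thresholds=roc_thr,
        recall=recall, precision=precision, pr_thresholds=pr_thr,
        auroc=auroc, aupr=aupr,
    )


def confusion_at_threshold(
    scores: EdgeFrequencyMatrix, gold: GoldStandard, threshold: float
) -> ConfusionSummary:
    """TPR, FPR and precision when edges scoring >= threshold are called."""
    y_true, y_score = _flatten_off_diagonal(scores, gold)
    predicted = y_score >= threshold
    tp = int(np.sum(predicted & (y_true == 1)))
    fp = int(np.sum(predicted & (y_true == 0)))
    n_pos = int(y_true.sum())
    n_neg = int(len(y_true) - n_pos)
    n_predicted = int(predicted.sum())
    defined = n_predicted > 0
    return ConfusionSummary(
        tpr=tp / n_pos,
        fpr=fp / n_neg,
        precision=tp / n_predicted if defined else float("nan"),
        precision_defined=defined,
        n_predicted=n_predicted,
    )
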