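"""Confusion-matrix metrics and rank-based AUC.

Accuracy, precision, recall and F1 are computed from the 2x2 confusion
tally; the AUC is the Mann-Whitney pair statistic

    AUC = 1 - (1 / m+ m-) * [ #{(x+, x-): f(x+) < f(x-)}
                              + 1/2 * #{(x+, x-): f(x+) = f(x-)} ],

i.e. the probability that a random positive outscores a random negative,
with ties counted half.  Multiclass scores are summarized macro one-vs-rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Per-class confusion counts plus (macro-)averaged summary metrics."""

    per_class: dict = field(default_factory=dict)  # label -> ConfusionCounts
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    auc: float = float("nan")
    averaging: str = "binary"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "averaging": self.averaging,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "per_class": {
                str(k): {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for k, c in self.per_class.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def confusion_counts(predicted, truth, positive_class) -> ConfusionCounts:
    """Standard 2x2 tally of predictions against truth for one positive class."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty evaluation")
    p = predicted == positive_class
    t = truth == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1); zero-denominator cases yield 0."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        logger.warning("no positive predictions; precision set to 0 by convention")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.warning("no positive truths; recall set to 0 by convention")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def auc_binary(scores, truth) -> float:
    """Rank-based AUC with the half-credit tie correction.

    Computed from midranks (Mann-Whitney U), which equals explicit
    enumeration of all positive-negative score pairs.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    m_pos = int(truth.sum())
    m_neg = int((~truth).sum())
    if m_pos == 0 or m_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative sample")
    ranks = rankdata(scores)  # midranks handle ties exactly as the half-pair term
    u = ranks[truth].sum() - m_pos * (m_pos + 1) / 2
    return float(u / (m_pos * m_neg))


def auc_macro_ovr(score_matrix, truth, classes=None) -> float:
    """Macro one-vs-rest AUC: mean of per-class binary AUCs.

    ``score_matrix`` is (n_samples, n_classes); classes absent from
    ``truth`` are excluded with a warning.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    truth = np.asarray(truth)
    if classes is None:
        classes = list(range(score_matrix.shape[1]))
    present = [k for k, c in enumerate(classes) if np.any(truth == c)]
    if len(present) < 2:
        raise ValueError("macro AUC needs at least two classes present in truth")
    for k, c in enumerate(classes):
        if k not in present:
            logger.warning("class %r absent from truth; excluded from macro AUC", c)
    aucs = [auc_binary(score_matrix[:, k], truth == classes[k]) for k in present]
    return float(np.mean(aucs))


def evaluate_predictions(
    truth, predicted, score_matrix=None, classes=None
) -> MetricsReport:
    """Build a full report: per-class confusion counts, averaged metrics, AUC.

    Two classes → binary metrics on the second class (with scores, its
    column's AUC); more → macro averages over one-vs-rest tallies.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = sorted(set(truth.tolist()) | set(predicted.tolist()))
    per_class = {c: confusion_counts(predicted, truth, c) for c in classes}

    if len(classes) == 2:
        counts = per_class[classes[1]]
        accuracy, precision, recall, f1 = classification_metrics(counts)
        auc = float("nan")
        if score_matrix is not None:
            s = np.asarray(score_matrix, dtype=float)
            pos = s[:, 1] if s.ndim == 2 else s
            auc = auc_binary(pos, truth == classes[1])
        return MetricsReport(per_class, accuracy, precision, recall, f1, auc, "binary")

    metrics = np.array([classification_metrics(per_class[c]) for c in classes])
    accuracy = float(np.mean(predicted == truth))  # overall multiclass accuracy
    precision, recall, f1 = (float(v) for v in metrics[:, 1:].mean(axis=0))
    auc = float("nan")
    if score_matrix is not None:
        auc = auc_macro_ovr(score_matrix, truth, classes)
    return MetricsReport(per_class, accuracy, precision, recall, f1, auc, "macro")
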