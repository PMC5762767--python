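"""Ranking-based multi-label evaluation: coverage, ranking loss, average precision.

All three consume a :class:`~sdamll.datamodel.RankedPrediction` (real scores,
larger = more relevant) and per-instance label subsets.  Ranks use the
deterministic index tie-break documented on ``RankedPrediction``; ranking
loss is computed from raw scores with ties counted as violations (the pair
condition is f(y1) <= f(y2)), which the index tie-break preserves.

Instances whose label set is empty or equals the full universe are rejected:
the pair-based quantities are undefined there.  Callers (the CV harness)
filter degenerate instances before evaluating.
"""
from __future__ import annotations

import numpy as np

from .datamodel import MetricsReport, MultiLabelDataset, RankedPrediction

__all__ = [
    "rank_of",
    "coverage",
    "ranking_loss",
    "average_precision",
    "evaluate_all",
]


def rank_of(scores: np.ndarray, label: int) -> int:
    """Rank (1 = best) of 1-based ``label`` within one score vector."""
    scores = np.asarray(scores, dtype=float)
    N = scores.shape[0]
    if not 1 <= label <= N:
        raise ValueError(f"label {label} outside 1..{N}")
    j = label - 1
    greater = int(np.sum(scores > scores[j]))
    tied_before = int(np.sum(scores[:j] == scores[j]))
    return 1 + greater + tied_before


def _as_label_matrix(labels, n_labels: int) -> np.ndarray:
    if isinstance(labels, MultiLabelDataset):
        return labels.label_matrix()
    Y = np.zeros((len(labels), n_labels), dtype=bool)
    for i, yset in enumerate(labels):
        for lab in yset:
            if not 1 <= lab <= n_labels:
                raise ValueError(f"label {lab} outside 1..{n_labels} at instance {i}")
            Y[i, lab - 1] = True
    return Y


def _check(pred: RankedPrediction, Y: np.ndarray, forbid_full: bool) -> None:
    if Y.shape != pred.scores.shape:
        raise ValueError(f"labels shape {Y.shape} != scores shape {pred.scores.shape}")
    sizes = Y.sum(axis=1)
    if np.any(sizes == 0):
        i = int(np.argmax(sizes == 0))
        raise ValueError(f"empty label set at instance {i}: metrics undefined")
    if forbid_full and np.any(sizes == Y.shape[1]):
        i = int(np.argmax(sizes == Y.shape[1]))
        raise ValueError(
            f"instance {i} carries every label: pairwise quantities undefined"
        )


def coverage(pred: RankedPrediction, labels) -> float:
    """Mean over instances of max_{l in Y_i} rank(x_i, l), minus 1."""
    Y = _as_label_matrix(labels, pred.n_labels)
    _check(pred, Y, forbid_full=False)
    ranks = pred.ranks()
    worst = np.where(Y, ranks, 0).max(axis=1)
    return float(worst.mean() - 1.0)


def ranking_loss(pred: RankedPrediction, labels) -> float:
    """Mean fraction of (relevant, irrelevant) pairs with f(rel) <= f(irr)."""
    Y = _as_label_matrix(labels, pred.n_labels)
    _check(pred, Y, forbid_full=True)
    s = pred.scores
    # leq[i, k, l] = (s_ik <= s_il); pair mask: k relevant, l irrelevant
    leq = s[:, :, None] <= s[:, None, :]
    pairmask = Y[:, :, None] & ~Y[:, None, :]
    nviol = (leq & pairmask).sum(axis=(1, 2))
    npairs = pairmask.sum(axis=(1, 2))
    return float((nviol / npairs).mean())


def average_precision(pred: RankedPrediction, labels) -> float:
    """Label-ranking average precision.

    For each true label l: the fraction of labels ranked at or above l
    that are themselves true, averaged over l in Y_i and over instances.
    """
    Y = _as_label_matrix(labels, pred.n_labels)
    _check(pred, Y, forbid_full=False)
    ranks = pred.ranks()
    total = 0.0
    for i in range(Y.shape[0]):
        rel_ranks = np.sort(ranks[i][Y[i]])
        # j-th smallest relevant rank has exactly j+1 relevant labels at
        # or above it (ranks are a permutation, so no duplicates)
        prec = (np.arange(1, rel_ranks.size + 1) / rel_ranks).mean()
        total += prec
    return total / Y.shape[0]


def evaluate_all(pred: RankedPrediction, labels) -> MetricsReport:
    """All three metrics in one report."""
    Y = _as_label_matrix(labels, pred.n_labels)
    return MetricsReport(
        coverage=coverage(pred, labels),
        ranking_loss=ranking_loss(pred, labels),
        average_precision=average_precision(pred, labels),
        m=int(Y.shape[0]),
    )
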