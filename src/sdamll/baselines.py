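"""Classical multi-label baselines: K-nearest neighbours and decision trees.

Both are adapted to multi-label output by binary relevance — each label is
scored independently — which yields the real-valued per-label scores the
ranking metrics require.  Both are fully deterministic: KNN breaks distance
ties by training-instance index, and tree induction is seeded-but-exact
(no randomness enters the greedy Gini splits).
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeClassifier

from .datamodel import MultiLabelDataset, RankedPrediction

__all__ = ["knn_scores", "dt_scores"]


def knn_scores(train: MultiLabelDataset, X: np.ndarray, k: int = 10) -> RankedPrediction:
    """score(x, l) = fraction of x's k Euclidean nearest training instances
    whose label set contains l.  Distance ties break by training index."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > train.n_instances:
        raise ValueError(f"k={k} exceeds training size {train.n_instances}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = cdist(X, train.features, metric="euclidean")
    # stable argsort: equal distances keep ascending training index
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    Ymat = train.label_matrix().astype(float)
    scores = Ymat[nbrs].mean(axis=1)
    return RankedPrediction(scores=scores)


def dt_scores(
    train: MultiLabelDataset,
    X: np.ndarray,
    depth: int | None = None,
    min_samples_leaf: int = 2,
) -> RankedPrediction:
    """One axis-aligned Gini tree per label (binary relevance); the score is
    the positive fraction in the reached leaf.

    ``depth=None`` grows until purity subject to ``min_samples_leaf`` (the
    default adaptation when no depth is imposed).
    """
    if depth is not None and depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Ymat = train.label_matrix()
    scores = np.empty((X.shape[0], train.n_labels))
    for j in range(train.n_labels):
        y = Ymat[:, j].astype(int)
        if y.min() == y.max():
            # constant label: every leaf is the root; score = prevalence
            scores[:, j] = float(y[0])
            continue
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=depth,
            min_samples_leaf=min_samples_leaf,
            random_state=0,
        )
        tree.fit(train.features, y)
        proba = tree.predict_proba(X)
        scores[:, j] = proba[:, list(tree.classes_).index(1)]
    return RankedPrediction(scores=scores)
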