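"""Core domain types for multi-label gene→pathway annotation.

A dataset couples a term-frequency feature matrix, scaled to the unit
interval, with one non-empty pathway-label subset per gene.  Labels are
1-based indices into ``label_names``; serialized files always use the
names, never the indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiLabelDataset",
    "RankedPrediction",
    "MetricsReport",
    "validate_dataset",
    "rescale_unit_interval",
]


@dataclass
class MultiLabelDataset:
    """Instances x_i in [0,1]^d with label subsets Y_i ⊆ {1..N}.

    Parameters
    ----------
    features : (m, d) float array, values in [0, 1]
    labels : per-instance frozensets of 1-based label indices
    label_names, feature_names, instance_ids : identifier strings
    """

    features: np.ndarray
    labels: list
    label_names: list
    feature_names: list
    instance_ids: list

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = [frozenset(y) for y in self.labels]

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def label_matrix(self) -> np.ndarray:
        """Boolean (m, N) indicator matrix of label membership."""
        Y = np.zeros((self.n_instances, self.n_labels), dtype=bool)
        for i, yset in enumerate(self.labels):
            for lab in yset:
                Y[i, lab - 1] = True
        return Y

    def degenerate_mask(self) -> np.ndarray:
        """True where Y_i = {1..N}: valid data, but the pairwise error
        is undefined (the complement set is empty), so training and the
        ranking metrics skip or reject those instances."""
        N = self.n_labels
        return np.array([len(y) == N for y in self.labels], dtype=bool)

    def subset(self, idx) -> "MultiLabelDataset":
        idx = np.asarray(idx)
        return MultiLabelDataset(
            features=self.features[idx],
            labels=[self.labels[i] for i in idx],
            label_names=list(self.label_names),
            feature_names=list(self.feature_names),
            instance_ids=[self.instance_ids[i] for i in idx],
        )

    def with_features(self, X: np.ndarray, feature_names=None) -> "MultiLabelDataset":
        """Same instances/labels over a new feature space (e.g. encoder codes)."""
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_instances:
            raise ValueError("row count mismatch")
        if feature_names is None:
            feature_names = [f"z{j}" for j in range(X.shape[1])]
        return MultiLabelDataset(
            features=X,
            labels=list(self.labels),
            label_names=list(self.label_names),
            feature_names=list(feature_names),
            instance_ids=list(self.instance_ids),
        )


def validate_dataset(ds: MultiLabelDataset) -> list:
    """Return one violation description per broken invariant (empty = valid).

    Reports rather than throws, so callers can surface all problems at once.
    """
    violations = []
    m, d = ds.features.shape
    N = ds.n_labels
    if len(ds.labels) != m:
        violations.append(
            f"label rows ({len(ds.labels)}) != feature rows ({m})"
        )
    if len(ds.feature_names) != d:
        violations.append(f"{len(ds.feature_names)} feature names for {d} columns")
    if len(ds.instance_ids) != m:
        violations.append(f"{len(ds.instance_ids)} instance ids for {m} rows")
    if not np.all(np.isfinite(ds.features)):
        i, j = np.argwhere(~np.isfinite(ds.features))[0]
        violations.append(f"non-finite feature at instance {i}, column {j}")
    else:
        bad = np.argwhere((ds.features < 0.0) | (ds.features > 1.0))
        for i, j in bad[:20]:
            violations.append(
                f"feature value {ds.features[i, j]!r} outside [0,1] at "
                f"instance {i}, column {j}"
            )
        if len(bad) > 20:
            violations.append(f"... and {len(bad) - 20} more out-of-range cells")
    for i, yset in enumerate(ds.labels[: m]):
        if len(yset) == 0:
            violations.append(f"empty label set at instance {i}")
        elif not all(1 <= lab <= N for lab in yset):
            violations.append(
                f"label index outside 1..{N} at instance {i}: {sorted(yset)}"
            )
    return violations


def rescale_unit_interval(X: np.ndarray) -> np.ndarray:
    """Column-wise max scaling into [0,1]; all-zero columns stay 0.

    Convenience for callers with raw non-negative counts: the encoder input
    contract is x in [0,1]^d.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("rescale_unit_interval expects non-negative values")
    colmax = X.max(axis=0)
    colmax[colmax == 0.0] = 1.0
    return X / colmax


@dataclass
class RankedPrediction:
    """Real-valued per-label scores with a deterministic rank function.

    Rank 1 is the highest score.  Ties are broken by ascending label
    index, giving a total order; this is pessimistic for ranking loss
    (tied relevant/irrelevant pairs count as mis-ordered there) and it is
    the convention constant-score models (all outputs 0.5) fall into.
    """

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))

    @property
    def n_instances(self) -> int:
        return self.scores.shape[0]

    @property
    def n_labels(self) -> int:
        return self.scores.shape[1]

    def ranks(self) -> np.ndarray:
        """(m, N) integer ranks in 1..N per instance (a permutation each)."""
        # stable sort on -scores: ties keep ascending label index
        order = np.argsort(-self.scores, axis=1, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(
            ranks, order, np.arange(1, self.n_labels + 1)[None, :], axis=1
        )
        return ranks


@dataclass
class MetricsReport:
    """The three ranking metrics over a dataset.

    coverage: mean over instances of (worst rank among true labels) − 1;
    in [0, N−1], lower is better.  ranking_loss: mean fraction of
    (relevant, irrelevant) pairs ordered incorrectly (ties count as
    incorrect); in [0,1], 0 is perfect.  average_precision: label-ranking
    average precision; in (0,1], 1 is perfect.
    """

    coverage: float
    ranking_loss: float
    average_precision: float
    m: int

    def to_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "ranking_loss": self.ranking_loss,
            "average_precision": self.average_precision,
            "m": self.m,
        }
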