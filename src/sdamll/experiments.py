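"""K-fold cross-validation comparison harness and permutation nulls.

The harness mirrors the reference protocol: the dataset is randomly split
into k (default 10) folds; each fold in turn is the validation set, every
method fits on the remaining folds and scores the validation instances,
and the three ranking metrics are computed per fold.  Aggregation reports
the mean and standard deviation over folds, and the pooled out-of-fold
scores are retained so a single dataset-level metric (and its permutation
null) can also be computed.

A *method* here is any callable ``(train: MultiLabelDataset, X_val, seed)
-> (m_val, N) score array``; built-in factories wrap SdaMLL, plain BP-MLL
(the empty-stack path of the same code), KNN and decision trees.

The permutation null reassigns whole label sets across instances, leaving
scores fixed: it is the distribution of a metric when predictions carry no
label information, the "no better than chance" reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines, bpmll, metrics
from . import model as sdamll_model
from .datamodel import MetricsReport, MultiLabelDataset, RankedPrediction

__all__ = [
    "CvResult",
    "PermutationNull",
    "kfold_split",
    "run_comparison",
    "permutation_null",
    "make_sdamll_method",
    "make_bpmll_method",
    "make_knn_method",
    "make_dt_method",
]


def kfold_split(m: int, k: int, seed: int) -> list:
    """Seeded random partition of range(m) into k folds of near-equal size
    (⌊m/k⌋ or ⌈m/k⌉; the first m mod k folds take the extra instance)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} folds requested for only m={m} instances")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


@dataclass
class CvResult:
    """Per-fold metrics per method plus the Table-style mean ± sd grid."""

    per_fold: dict                 # method -> list[MetricsReport | None]
    summary: dict                  # method -> {metric: {"mean":…, "sd":…}}
    folds: list                    # index arrays
    pooled: dict                   # method -> RankedPrediction over all rows
    pooled_labels: list            # label sets aligned with pooled scores
    failures: list = field(default_factory=list)  # (method, fold, message)
    seed: int = 0

    def pooled_report(self, method: str) -> MetricsReport:
        return metrics.evaluate_all(self.pooled[method], self.pooled_labels)


_METRIC_NAMES = ("average_precision", "ranking_loss", "coverage")


def run_comparison(ds: MultiLabelDataset, methods: dict, k: int = 10, seed: int = 0) -> CvResult:
    """Fit every method on each training split, score the held-out fold,
    evaluate the three ranking metrics, and aggregate.

    Degenerate validation instances (full label set) are excluded from the
    metric computation — the pairwise quantities are undefined for them.
    A method failure on a fold is recorded and the run continues.
    """
    m = ds.n_instances
    folds = kfold_split(m, k, seed)
    ok = ~ds.degenerate_mask()
    per_fold = {name: [] for name in methods}
    pooled_scores = {name: np.full((m, ds.n_labels), np.nan) for name in methods}
    failures = []
    method_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(sorted(methods), np.random.SeedSequence(seed).spawn(len(methods)))
    }
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(m), val_idx)
        train_ds = ds.subset(train_idx)
        X_val = ds.features[val_idx]
        eval_idx = val_idx[ok[val_idx]]
        eval_labels = [ds.labels[i] for i in eval_idx]
        for name, method in methods.items():
            try:
                scores = np.asarray(
                    method(train_ds, X_val, method_seeds[name] + fi)
                )
                pooled_scores[name][val_idx] = scores
                pred = RankedPrediction(scores=scores[ok[val_idx]])
                per_fold[name].append(metrics.evaluate_all(pred, eval_labels))
            except Exception as exc:  # noqa: BLE001 - fold marked invalid, run continues
                failures.append((name, fi, str(exc)))
                per_fold[name].append(None)
    summary = {}
    for name in methods:
        reports = [r for r in per_fold[name] if r is not None]
        summary[name] = {
            metric: {
                "mean": float(np.mean([getattr(r, metric) for r in reports]))
                if reports else float("nan"),
                "sd": float(np.std([getattr(r, metric) for r in reports], ddof=1))
                if len(reports) > 1 else float("nan"),
            }
            for metric in _METRIC_NAMES
        }
    keep = ok.copy()
    for name in methods:
        keep &= ~np.isnan(pooled_scores[name]).any(axis=1)
    pooled = {
        name: RankedPrediction(scores=pooled_scores[name][keep]) for name in methods
    }
    return CvResult(
        per_fold=per_fold,
        summary=summary,
        folds=folds,
        pooled=pooled,
        pooled_labels=[ds.labels[i] for i in np.flatnonzero(keep)],
        failures=failures,
        seed=seed,
    )


@dataclass
class PermutationNull:
    mean: float
    sd: float
    quantiles: dict
    values: np.ndarray

    def central_interval(self, level: float = 0.95):
        lo = (1.0 - level) / 2.0 * 100.0
        return (
            float(np.percentile(self.values, lo)),
            float(np.percentile(self.values, 100.0 - lo)),
        )


def permutation_null(ds: MultiLabelDataset, statistic, n_perm: int = 200, seed: int = 0) -> PermutationNull:
    """Distribution of ``statistic`` under random reassignment of whole
    label sets across instances.

    ``statistic`` is a callable taking the permuted dataset.  Requires
    n_perm >= 100 so tail quantiles are estimable.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    m = ds.n_instances
    values = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(m)
        permuted = MultiLabelDataset(
            features=ds.features,
            labels=[ds.labels[i] for i in perm],
            label_names=ds.label_names,
            feature_names=ds.feature_names,
            instance_ids=ds.instance_ids,
        )
        values[p] = statistic(permuted)
    qs = {q: float(np.percentile(values, q)) for q in (2.5, 25.0, 50.0, 75.0, 97.5)}
    return PermutationNull(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        quantiles=qs,
        values=values,
    )


def score_permutation_null(
    pred: RankedPrediction, labels, metric, n_perm: int = 200, seed: int = 0
) -> PermutationNull:
    """Null for a ranking metric of *fixed* scores against shuffled label
    sets — the standard chance reference for held-out predictions."""
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    labels = list(labels)
    m = len(labels)
    values = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(m)
        values[p] = metric(pred, [labels[i] for i in perm])
    qs = {q: float(np.percentile(values, q)) for q in (2.5, 25.0, 50.0, 75.0, 97.5)}
    return PermutationNull(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        quantiles=qs,
        values=values,
    )


# ---------------------------------------------------------------- methods

def make_sdamll_method(cfg: sdamll_model.SdamllConfig | None = None):
    """SdaMLL: pretrain stack + BP-MLL on codes, per-fold."""

    def method(train_ds: MultiLabelDataset, X_val: np.ndarray, seed: int):
        mcfg = cfg or sdamll_model.SdamllConfig()
        mcfg = sdamll_model.SdamllConfig.from_dict(mcfg.to_dict())
        mcfg.dae.seed = seed
        mcfg.bpmll.seed = seed + 1
        fitted = sdamll_model.fit(train_ds, mcfg)
        return sdamll_model.predict(fitted, X_val).scores

    return method


def make_bpmll_method(cfg: bpmll.BpmllTrainConfig | None = None):
    """Plain BP-MLL on raw features — the empty-stack path of SdaMLL."""

    def method(train_ds: MultiLabelDataset, X_val: np.ndarray, seed: int):
        base = cfg or bpmll.BpmllTrainConfig()
        d = train_ds.n_features
        mcfg = sdamll_model.SdamllConfig(
            layer_sizes=[d],
            bpmll=bpmll.BpmllTrainConfig(**(vars(base) | {"seed": seed})),
        )
        fitted = sdamll_model.fit(train_ds, mcfg)
        return sdamll_model.predict(fitted, X_val).scores

    return method


def make_knn_method(k: int = 10):
    def method(train_ds, X_val, seed):  # deterministic; seed unused
        return baselines.knn_scores(train_ds, X_val, k=k).scores

    return method


def make_dt_method(depth: int | None = None, min_samples_leaf: int = 2):
    def method(train_ds, X_val, seed):  # deterministic; seed unused
        return baselines.dt_scores(
            train_ds, X_val, depth=depth, min_samples_leaf=min_samples_leaf
        ).scores

    return method
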