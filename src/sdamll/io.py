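"""Readers/writers for feature matrices, label tables, reports and manifests.

Features travel either as dense TSV (header row = feature names, first
column = instance id) or as MatrixMarket sparse (.mtx) with two sidecar
text files ``<path>.rows`` / ``<path>.cols`` holding instance ids and
feature names, one per line.  Labels are TSV with two columns:
instance_id and a comma-separated list of label names.  All text is UTF-8.

Numeric TSV cells are formatted with 9 significant digits, which makes
write→read→write stable byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datamodel import MultiLabelDataset, RankedPrediction, rescale_unit_interval

__all__ = [
    "read_features",
    "write_features",
    "read_labels",
    "write_labels",
    "assemble_dataset",
    "load_dataset",
    "write_scores",
    "read_scores",
    "write_manifest",
]

_FMT = "%.9g"


def _infer_format(path: str) -> str:
    return "mtx" if str(path).endswith(".mtx") else "tsv"


def _validate_range(X: np.ndarray, rescale: bool, source: str) -> np.ndarray:
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"{source}: negative value {X[i, j]!r} at row {i}, column {j}"
        )
    if np.any(X > 1.0):
        if rescale:
            return rescale_unit_interval(X)
        i, j = np.argwhere(X > 1.0)[0]
        raise ValueError(
            f"{source}: value {X[i, j]!r} > 1 at row {i}, column {j}; "
            "pass rescale=True (--rescale) to max-scale columns into [0,1]"
        )
    return X


def read_features(path: str, fmt: str | None = None, rescale: bool = False):
    """-> (X, feature_names, instance_ids); values validated into [0,1]."""
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
            X = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"malformed feature TSV {path}: {exc}") from exc
        names = [str(c) for c in df.columns]
        ids = [str(i) for i in df.index]
    elif fmt == "mtx":
        M = sio.mmread(path)
        X = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
        ids = _read_sidecar(path + ".rows", X.shape[0], "gene")
        names = _read_sidecar(path + ".cols", X.shape[1], "term")
    else:
        raise ValueError(f"unknown feature format {fmt!r}")
    X = _validate_range(X, rescale, path)
    return X, names, ids


def _read_sidecar(path: str, n: int, prefix: str):
    if os.path.exists(path):
        with open(path, encoding="utf-8") as fh:
            names = [line.rstrip("\n") for line in fh if line.strip()]
        if len(names) != n:
            raise ValueError(f"{path}: {len(names)} names for {n} entries")
        return names
    return [f"{prefix}_{i:05d}" for i in range(n)]


def write_features(path: str, X: np.ndarray, feature_names, instance_ids, fmt: str | None = None):
    fmt = fmt or _infer_format(path)
    X = np.asarray(X, dtype=float)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("instance_id\t" + "\t".join(feature_names) + "\n")
            for rid, row in zip(instance_ids, X):
                fh.write(rid + "\t" + "\t".join(_FMT % v for v in row) + "\n")
    elif fmt == "mtx":
        sio.mmwrite(path, sp.coo_matrix(X))
        for side, names in ((".rows", instance_ids), (".cols", feature_names)):
            with open(path + side, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("\n".join(names) + "\n")
    else:
        raise ValueError(f"unknown feature format {fmt!r}")


def read_labels(path: str):
    """-> (instance_ids, label_sets_by_name, label_names sorted)."""
    ids, sets = [], []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("instance_id"):
            raise ValueError(f"{path}: expected header starting with 'instance_id'")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path} line {ln}: expected 2 tab-separated columns")
            rid, cell = parts
            if rid in seen:
                raise ValueError(f"{path} line {ln}: duplicate instance id {rid!r}")
            seen.add(rid)
            names = [t.strip() for t in cell.split(",")]
            if not all(names) or not names:
                raise ValueError(f"{path} line {ln}: empty label cell for {rid!r}")
            ids.append(rid)
            sets.append(frozenset(names))
    universe = sorted(set().union(*sets)) if sets else []
    return ids, sets, universe


def write_labels(path: str, instance_ids, label_sets, label_names):
    """label_sets: per-instance frozensets of 1-based indices into label_names."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\tlabels\n")
        for rid, yset in zip(instance_ids, label_sets):
            names = sorted(label_names[lab - 1] for lab in yset)
            fh.write(f"{rid}\t{','.join(names)}\n")


def assemble_dataset(X, feature_names, feature_ids, label_ids, label_sets_by_name, label_names):
    """Join features and labels on instance id (features define row order)."""
    lab_by_id = dict(zip(label_ids, label_sets_by_name))
    missing = [rid for rid in feature_ids if rid not in lab_by_id]
    if missing:
        raise ValueError(f"instances in features but not labels: {missing[:5]}")
    extra = [rid for rid in label_ids if rid not in set(feature_ids)]
    if extra:
        raise ValueError(f"instances in labels but not features: {extra[:5]}")
    index = {name: j + 1 for j, name in enumerate(label_names)}
    labels = []
    for rid in feature_ids:
        names = lab_by_id[rid]
        unknown = [n for n in names if n not in index]
        if unknown:
            raise ValueError(f"unknown label name(s) {unknown} for instance {rid!r}")
        labels.append(frozenset(index[n] for n in names))
    return MultiLabelDataset(
        features=X,
        labels=labels,
        label_names=list(label_names),
        feature_names=list(feature_names),
        instance_ids=list(feature_ids),
    )


def load_dataset(features_path: str, labels_path: str, rescale: bool = False) -> MultiLabelDataset:
    X, fnames, fids = read_features(features_path, rescale=rescale)
    lids, lsets, universe = read_labels(labels_path)
    return assemble_dataset(X, fnames, fids, lids, lsets, universe)


def write_scores(path: str, pred: RankedPrediction, instance_ids, label_names):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\t" + "\t".join(label_names) + "\n")
        for rid, row in zip(instance_ids, pred.scores):
            fh.write(rid + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def read_scores(path: str):
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    return (
        RankedPrediction(scores=df.to_numpy(dtype=float)),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str, command: str, config: dict, inputs: dict):
    """Record everything needed to reproduce a run: command, full config
    (seeds included), input digests, and library versions."""
    import sklearn

    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "versions": {
            "sdamll": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
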