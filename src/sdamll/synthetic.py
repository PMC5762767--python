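"""Synthetic multi-label term-frequency corpora.

Emulates the statistical structure of a literature-mined gene×term matrix:
high-dimensional, sparse (most cells exactly zero), where each pathway
label induces an enriched "signature" set of terms.  Counts are Poisson —
mean ``signal_strength`` on signature terms of the labels a gene owns,
mean ``background_rate`` elsewhere — then column-max scaled into [0,1].

This is deliberately not a text model: no Zipf law, no document structure.
It provides exactly the features the downstream method assumes (bounded
non-negative term frequencies with label-linked enrichment) and nothing
more, so recovery tests have a clean, known ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MultiLabelDataset, rescale_unit_interval

__all__ = ["SyntheticSpec", "validate_spec", "generate"]


def _default_cardinality_dist():
    # uniform over 1..3 labels per gene
    return {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}


@dataclass
class SyntheticSpec:
    """Generator parameters.

    ``labels_per_instance`` maps label-set cardinality (in 1..N−1, never N,
    so the pairwise error is always defined) to its probability.
    ``signature_overlap`` is the fraction of each label's signature block
    shared with its neighbour; 0 (default) keeps signatures disjoint.
    """

    n_instances: int = 500
    n_labels: int = 8
    n_terms: int = 2000
    signature_terms_per_label: int = 25
    labels_per_instance: dict = field(default_factory=_default_cardinality_dist)
    signal_strength: float = 5.0
    background_rate: float = 0.05
    signature_overlap: float = 0.0
    seed: int = 0


def validate_spec(spec: SyntheticSpec) -> list:
    """One entry per violated constraint; empty when the spec is usable."""
    v = []
    if spec.n_labels < 2:
        v.append(f"n_labels must be >= 2, got {spec.n_labels}")
    if spec.n_instances < 1:
        v.append(f"n_instances must be >= 1, got {spec.n_instances}")
    if spec.signature_terms_per_label * spec.n_labels > spec.n_terms:
        v.append(
            f"signature_terms_per_label*n_labels = "
            f"{spec.signature_terms_per_label * spec.n_labels} exceeds "
            f"n_terms = {spec.n_terms}"
        )
    if not spec.signal_strength >= spec.background_rate >= 0.0:
        v.append(
            f"need signal_strength >= background_rate >= 0, got "
            f"{spec.signal_strength} / {spec.background_rate}"
        )
    if not 0.0 <= spec.signature_overlap < 1.0:
        v.append(f"signature_overlap must be in [0,1), got {spec.signature_overlap}")
    card = spec.labels_per_instance
    if not card:
        v.append("labels_per_instance is empty")
    else:
        if any(not 1 <= int(k) <= spec.n_labels - 1 for k in card):
            v.append(
                f"labels_per_instance cardinalities must lie in "
                f"1..{spec.n_labels - 1}, got {sorted(card)}"
            )
        if any(p < 0 for p in card.values()) or not np.isclose(
            sum(card.values()), 1.0
        ):
            v.append("labels_per_instance probabilities must be >= 0 and sum to 1")
    return v


def signature_terms(spec: SyntheticSpec) -> dict:
    """1-based label -> array of 0-based signature term columns."""
    s = spec.signature_terms_per_label
    step = max(1, int(round(s * (1.0 - spec.signature_overlap))))
    return {
        lab: np.arange((lab - 1) * step, (lab - 1) * step + s)
        for lab in range(1, spec.n_labels + 1)
    }


def generate(spec: SyntheticSpec) -> MultiLabelDataset:
    """Draw one dataset; deterministic given ``spec.seed``."""
    problems = validate_spec(spec)
    if problems:
        raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    rng = np.random.default_rng(spec.seed)
    n, N, d = spec.n_instances, spec.n_labels, spec.n_terms

    cards = sorted(int(k) for k in spec.labels_per_instance)
    probs = np.array([spec.labels_per_instance[k] for k in cards], dtype=float)
    probs = probs / probs.sum()
    sizes = rng.choice(cards, size=n, p=probs)
    labels = [
        frozenset(int(l) + 1 for l in rng.choice(N, size=k, replace=False))
        for k in sizes
    ]

    counts = rng.poisson(spec.background_rate, size=(n, d)).astype(float)
    sig = signature_terms(spec)
    owns = np.zeros((n, N), dtype=bool)
    for i, yset in enumerate(labels):
        for lab in yset:
            owns[i, lab - 1] = True
    for lab in range(1, N + 1):
        rows = np.flatnonzero(owns[:, lab - 1])
        cols = sig[lab]
        if rows.size:
            counts[np.ix_(rows, cols)] = rng.poisson(
                spec.signal_strength, size=(rows.size, cols.size)
            )

    features = rescale_unit_interval(counts)
    return MultiLabelDataset(
        features=features,
        labels=labels,
        label_names=[f"pathway_{j}" for j in range(1, N + 1)],
        feature_names=[f"term_{j:05d}" for j in range(d)],
        instance_ids=[f"gene_{i:05d}" for i in range(n)],
    )
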