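"""Multi-label feed-forward network with the pairwise exponential error.

A single hidden layer of M sigmoid units maps x to hidden activations
b = s(Vᵀx + γ) and outputs c = s(Wᵀb + θ), one output per label.  The
per-instance error couples every (relevant, irrelevant) label pair:

    E_i = (1/(|Y_i||Ȳ_i|)) Σ_{(k,l) in Y_i × Ȳ_i} exp(−(c_k − c_l))

so any irrelevant label scored near or above a relevant one is penalized,
normalized by the number of pairs.  Training is online: instances are fed
one by one and every parameter takes a gradient step per instance;
training stops when the global error E = Σ_i E_i has not decreased for
``patience`` consecutive epochs or when ``max_epochs`` is reached.

The output-layer and hidden-layer deltas are the chain-rule derivatives of
E_i through the sigmoids; their correctness is pinned by central
finite-difference tests rather than taken on faith.  Using the identity
exp(−(c_k − c_l)) = e^{−c_k}·e^{c_l}, both E_i and the deltas reduce to
O(N) per instance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import sigmoid
from .datamodel import MultiLabelDataset, RankedPrediction

_log = logging.getLogger(__name__)

__all__ = [
    "BpmllNetwork",
    "BpmllTrainConfig",
    "forward",
    "instance_error",
    "global_error",
    "gradients",
    "init_network",
    "train_bpmll",
    "predict_scores",
    "predict_labels",
]


@dataclass
class BpmllNetwork:
    """Parameters: input→hidden weights V (d×M) and bias γ, hidden→output
    weights W (M×N) and bias θ.  Sigmoid activation at both layers."""

    V: np.ndarray            # (d, M), entry v_hs
    W: np.ndarray            # (M, N), entry w_sj
    hidden_bias: np.ndarray  # (M,), γ_s
    output_bias: np.ndarray  # (N,), θ_j

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.output_bias = np.asarray(self.output_bias, dtype=float)
        d, M = self.V.shape
        M2, N = self.W.shape
        if M != M2 or self.hidden_bias.shape != (M,) or self.output_bias.shape != (N,):
            raise ValueError("inconsistent parameter shapes")

    @property
    def d(self) -> int:
        return self.V.shape[0]

    @property
    def M(self) -> int:
        return self.V.shape[1]

    @property
    def N(self) -> int:
        return self.W.shape[1]


@dataclass
class BpmllTrainConfig:
    alpha: float = 0.05
    max_epochs: int = 30
    patience: int = 3
    M: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"learning rate alpha must lie in (0,1), got {self.alpha}")
        if self.max_epochs < 1 or self.patience < 1 or self.M < 1:
            raise ValueError("max_epochs, patience and M must be >= 1")


# strict-decrease tolerance for the stopping rule: avoids hair-trigger
# stops on float noise
_DECREASE_TOL = 1e-9


def forward(net: BpmllNetwork, x: np.ndarray):
    """Hidden activations b = s(Vᵀx + γ) and outputs c = s(Wᵀb + θ)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != net.d:
        raise ValueError(f"input has {x.shape[-1]} features, network expects {net.d}")
    b = sigmoid(x @ net.V + net.hidden_bias)
    c = sigmoid(b @ net.W + net.output_bias)
    return b, c


def _check_labels(Y: frozenset, N: int) -> tuple:
    Y = frozenset(Y)
    if not Y:
        raise ValueError("label set is empty: the pairwise error is undefined")
    if len(Y) == N:
        raise ValueError(
            "label set equals the full universe (complement empty): "
            "the pairwise error is undefined — skip this instance"
        )
    if not all(1 <= lab <= N for lab in Y):
        raise ValueError(f"label indices outside 1..{N}: {sorted(Y)}")
    rel = np.array(sorted(lab - 1 for lab in Y))
    irr = np.array(sorted(set(range(N)) - {lab - 1 for lab in Y}))
    return rel, irr


def instance_error(c: np.ndarray, Y) -> float:
    """E_i for one output vector and its (non-degenerate) label set."""
    c = np.asarray(c, dtype=float)
    rel, irr = _check_labels(Y, c.shape[0])
    # Σ exp(−(c_k − c_l)) factorizes over the product set
    return float(
        np.sum(np.exp(-c[rel])) * np.sum(np.exp(c[irr])) / (rel.size * irr.size)
    )


def global_error(net: BpmllNetwork, ds: MultiLabelDataset):
    """E = Σ_i E_i over usable instances.

    Degenerate instances (Y_i full) are skipped and counted; the count is
    returned alongside E so callers can surface it.
    """
    _, C = forward(net, ds.features)
    Ymat = ds.label_matrix()
    sizes = Ymat.sum(axis=1)
    usable = sizes < ds.n_labels
    n_skipped = int((~usable).sum())
    if n_skipped:
        _log.info("global_error: skipped %d full-label-set instance(s)", n_skipped)
    exp_neg = np.where(Ymat, np.exp(-C), 0.0).sum(axis=1)
    exp_pos = np.where(~Ymat, np.exp(C), 0.0).sum(axis=1)
    npairs = sizes * (ds.n_labels - sizes)
    per = np.where(usable, exp_neg * exp_pos / np.where(usable, npairs, 1), 0.0)
    return float(per.sum()), n_skipped


def _deltas(c: np.ndarray, rel: np.ndarray, irr: np.ndarray) -> np.ndarray:
    """d_j = −∂E_i/∂net_c_j for every output unit (chain rule through s)."""
    norm = rel.size * irr.size
    d = np.zeros_like(c)
    sum_irr = np.sum(np.exp(c[irr]))
    sum_rel = np.sum(np.exp(-c[rel]))
    d[rel] = np.exp(-c[rel]) * sum_irr / norm
    d[irr] = -np.exp(c[irr]) * sum_rel / norm
    return d * c * (1.0 - c)


def gradients(net: BpmllNetwork, x: np.ndarray, Y, alpha: float) -> dict:
    """Per-instance updates ΔW, ΔV, Δθ, Δγ (already scaled by α).

    ΔW_sj = α d_j b_s, ΔV_hs = α e_s a_h, Δθ_j = α d_j, Δγ_s = α e_s with
    d_j as in :func:`_deltas` and e_s = (Σ_j d_j w_sj)·b_s(1−b_s).
    Adding the updates to the parameters decreases E_i for small α.
    """
    x = np.asarray(x, dtype=float)
    rel, irr = _check_labels(Y, net.N)
    b, c = forward(net, x)
    d = _deltas(c, rel, irr)
    e = (net.W @ d) * b * (1.0 - b)
    return {
        "W": alpha * np.outer(b, d),
        "V": alpha * np.outer(x, e),
        "output_bias": alpha * d,
        "hidden_bias": alpha * e,
    }


def init_network(d: int, M: int, N: int, rng: np.random.Generator) -> BpmllNetwork:
    """Small uniform ±0.05 weights and biases, seeded."""
    return BpmllNetwork(
        V=rng.uniform(-0.05, 0.05, size=(d, M)),
        W=rng.uniform(-0.05, 0.05, size=(M, N)),
        hidden_bias=rng.uniform(-0.05, 0.05, size=M),
        output_bias=rng.uniform(-0.05, 0.05, size=N),
    )


def train_bpmll(ds: MultiLabelDataset, cfg: BpmllTrainConfig):
    """Online training with the pairwise exponential error.

    Returns the trained network and the trace of global E per epoch
    (entry 0 is E at initialization).  Stops when E has failed to decrease
    (strictly, beyond a 1e−9 tolerance) for ``patience`` consecutive
    epochs, or at ``max_epochs``.
    """
    usable = ~ds.degenerate_mask()
    if not usable.any():
        raise ValueError("no instance with a proper label subset: cannot train")
    n_skipped = int((~usable).sum())
    if n_skipped:
        _log.info("train_bpmll: skipping %d full-label-set instance(s)", n_skipped)
    idx_usable = np.flatnonzero(usable)

    rng = np.random.default_rng(cfg.seed)
    net = init_network(ds.n_features, cfg.M, ds.n_labels, rng)
    E0, _ = global_error(net, ds)
    trace = [E0]
    best = np.inf
    stall = 0
    for epoch in range(cfg.max_epochs):
        for i in rng.permutation(idx_usable):
            upd = gradients(net, ds.features[i], ds.labels[i], cfg.alpha)
            net.W += upd["W"]
            net.V += upd["V"]
            net.output_bias += upd["output_bias"]
            net.hidden_bias += upd["hidden_bias"]
        E, _ = global_error(net, ds)
        if not np.isfinite(E):
            raise FloatingPointError(
                f"non-finite global error at epoch {epoch + 1}; "
                f"alpha={cfg.alpha} is likely too large"
            )
        trace.append(E)
        if E < best - _DECREASE_TOL:
            best = E
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return net, trace


def predict_scores(net: BpmllNetwork, X: np.ndarray) -> RankedPrediction:
    """Network outputs c per row, as a ranked prediction."""
    _, C = forward(net, np.atleast_2d(np.asarray(X, dtype=float)))
    return RankedPrediction(scores=C)


def predict_labels(rp: RankedPrediction, rule: str = "threshold", t: int | None = None):
    """Set-valued predictions from scores (the ranking metrics don't need
    this; it is a convenience for consumers wanting hard assignments).

    rule="threshold": label predicted iff score > 0.5 (may be empty —
    allowed for predictions, logged).  rule="top_t": the t best-ranked
    labels per instance.
    """
    if rule == "threshold":
        out = [
            frozenset(int(j) + 1 for j in np.flatnonzero(row > 0.5))
            for row in rp.scores
        ]
        n_empty = sum(1 for y in out if not y)
        if n_empty:
            _log.info("predict_labels: %d instance(s) got an empty prediction", n_empty)
        return out
    if rule == "top_t":
        if t is None:
            raise ValueError("rule='top_t' requires t")
        ranks = rp.ranks()
        return [
            frozenset(int(j) + 1 for j in np.flatnonzero(r <= t)) for r in ranks
        ]
    raise ValueError(f"unknown rule {rule!r}")
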