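"""Denoising autoencoder with tied weights, plus greedy layer-wise stacking.

One layer maps x in [0,1]^d to a code y = s(Wx + b) in (0,1)^d' and back to
z = s(Wᵀy + b'); the sigmoid s(t) = 1/(1+e^{-t}) is used throughout and the
decoder weight is always the transpose of the encoder weight (tied — never
stored separately).  Training corrupts each input by zeroing exactly
⌊v·d⌋ randomly chosen coordinates, then takes a plain per-instance SGD step
on the reconstruction loss against the *clean* input.

Stacking is greedy: layer k+1 trains on the codes of the already-trained
first k layers, with corruption applied to that layer's own input.  At
transform time no corruption is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

_log = logging.getLogger(__name__)

__all__ = [
    "DenoisingAutoencoderParams",
    "CorruptionSpec",
    "DaeTrainConfig",
    "StackedEncoder",
    "sigmoid",
    "corrupt",
    "encode",
    "decode",
    "reconstruction_loss",
    "dae_gradients",
    "init_dae",
    "train_dae",
    "pretrain_stack",
    "transform",
]

_EPS = 1e-12
LOSS_KINDS = ("squared_error", "cross_entropy")


def sigmoid(t):
    return 1.0 / (1.0 + np.exp(-t))


@dataclass
class DenoisingAutoencoderParams:
    """θ = {W, b} for the encoder; the decoder reuses Wᵀ plus a free bias b'."""

    W: np.ndarray        # (d', d)
    b: np.ndarray        # (d',)
    b_prime: np.ndarray  # (d,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        d_hidden, d = self.W.shape
        if self.b.shape != (d_hidden,) or self.b_prime.shape != (d,):
            raise ValueError("bias shapes inconsistent with W")

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W.shape[0]


@dataclass
class CorruptionSpec:
    """Masking noise: a fixed count ⌊v·d⌋ of coordinates is zeroed."""

    v: float
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"corruption fraction v must be in [0,1], got {self.v}")

    def stream(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class DaeTrainConfig:
    epochs: int = 5
    learning_rate: float = 0.1
    loss_kind: str = "cross_entropy"
    v: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"corruption fraction v must be in [0,1], got {self.v}")


def corrupt(x: np.ndarray, cs: CorruptionSpec, rng: np.random.Generator | None = None):
    """Zero exactly ⌊v·d⌋ uniformly chosen coordinates; others untouched."""
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = cs.stream()
    d = x.shape[-1]
    n_zero = int(np.floor(cs.v * d))
    out = x.copy()
    if n_zero:
        idx = rng.choice(d, size=n_zero, replace=False)
        out[..., idx] = 0.0
    return out


def encode(p: DenoisingAutoencoderParams, x: np.ndarray) -> np.ndarray:
    """y = s(Wx + b).  Accepts a vector or an (m, d) matrix of rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != p.d:
        raise ValueError(f"input has {x.shape[-1]} features, layer expects {p.d}")
    return sigmoid(x @ p.W.T + p.b)


def decode(p: DenoisingAutoencoderParams, y: np.ndarray) -> np.ndarray:
    """z = s(Wᵀy + b') — tied weights, transpose of the encoder."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != p.d_hidden:
        raise ValueError(f"code has {y.shape[-1]} units, layer expects {p.d_hidden}")
    return sigmoid(y @ p.W + p.b_prime)


def reconstruction_loss(x: np.ndarray, z: np.ndarray, kind: str) -> float:
    """Σ(x−z)² or the cross-entropy −Σ[x ln z + (1−x) ln(1−z)].

    Cross-entropy reconstructions at exactly 0 or 1 are clamped to
    [ε, 1−ε], ε = 1e−12 (logged) — the sigmoid keeps z strictly inside
    (0,1) in exact arithmetic, but float rounding can saturate.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have the same shape")
    if kind == "squared_error":
        return float(np.sum((x - z) ** 2))
    if kind == "cross_entropy":
        if np.any((z <= 0.0) | (z >= 1.0)):
            _log.warning("cross_entropy reconstruction clamped to [%g, 1-%g]", _EPS, _EPS)
            z = np.clip(z, _EPS, 1.0 - _EPS)
        return float(-np.sum(x * np.log(z) + (1.0 - x) * np.log1p(-z)))
    raise ValueError(f"unknown loss kind {kind!r}")


def dae_gradients(p: DenoisingAutoencoderParams, x_tilde, x_clean, kind: str):
    """Loss gradients (dW, db, db') for one corrupted/clean pair.

    The decoder path's weight gradient accumulates into W (tied weights):
    dW = δ_hidden x̃ᵀ + y δ_outᵀ.
    """
    x_tilde = np.asarray(x_tilde, dtype=float)
    x_clean = np.asarray(x_clean, dtype=float)
    y = encode(p, x_tilde)
    z = decode(p, y)
    zc = np.clip(z, _EPS, 1.0 - _EPS)
    if kind == "squared_error":
        # dL/dz = 2(z - x); times z(1-z) for the output pre-activation
        delta_out = 2.0 * (z - x_clean) * z * (1.0 - z)
    elif kind == "cross_entropy":
        # dL/dnet_z simplifies to z - x for sigmoid + cross-entropy
        delta_out = zc - x_clean
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    delta_hidden = (p.W @ delta_out) * y * (1.0 - y)
    dW = np.outer(delta_hidden, x_tilde) + np.outer(y, delta_out)
    return dW, delta_hidden, delta_out


def init_dae(d: int, d_hidden: int, rng: np.random.Generator) -> DenoisingAutoencoderParams:
    """Uniform ±4·√(6/(d+d')) weights (standard sigmoid init), zero biases."""
    bound = 4.0 * np.sqrt(6.0 / (d + d_hidden))
    W = rng.uniform(-bound, bound, size=(d_hidden, d))
    return DenoisingAutoencoderParams(W=W, b=np.zeros(d_hidden), b_prime=np.zeros(d))


def mean_clean_loss(p: DenoisingAutoencoderParams, X: np.ndarray, kind: str) -> float:
    """Mean reconstruction loss of uncorrupted rows (the trace quantity)."""
    Z = decode(p, encode(p, X))
    X = np.asarray(X, dtype=float)
    if kind == "squared_error":
        per = np.sum((X - Z) ** 2, axis=1)
    else:
        Zc = np.clip(Z, _EPS, 1.0 - _EPS)
        per = -np.sum(X * np.log(Zc) + (1.0 - X) * np.log1p(-Zc), axis=1)
    return float(per.mean())


def train_dae(X: np.ndarray, cfg: DaeTrainConfig, d_hidden: int):
    """Per-instance SGD on the denoising objective.

    Each epoch shuffles the instance order, then for every row: corrupt →
    encode → decode → one gradient step against the clean row.  Returns
    the trained parameters and a per-epoch trace of the mean clean-input
    reconstruction loss (entry 0 is the loss at initialization).
    """
    X = np.asarray(X, dtype=float)
    m, d = X.shape
    rng = np.random.default_rng(cfg.seed)
    p = init_dae(d, d_hidden, rng)
    cs = CorruptionSpec(v=cfg.v)
    lr = cfg.learning_rate
    trace = [mean_clean_loss(p, X, cfg.loss_kind)]
    for epoch in range(cfg.epochs):
        for i in rng.permutation(m):
            x = X[i]
            xt = corrupt(x, cs, rng)
            dW, db, dbp = dae_gradients(p, xt, x, cfg.loss_kind)
            p.W -= lr * dW
            p.b -= lr * db
            p.b_prime -= lr * dbp
        loss = mean_clean_loss(p, X, cfg.loss_kind)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite reconstruction loss at epoch {epoch + 1}; "
                f"learning_rate={lr} is likely too large"
            )
        trace.append(loss)
    return p, trace


@dataclass
class StackedEncoder:
    """Ordered denoising-autoencoder layers d → h_1 → … → h_K."""

    layers: list = field(default_factory=list)
    layer_sizes: list = field(default_factory=list)
    loss_traces: list = field(default_factory=list)

    def __post_init__(self):
        dims = [self.layer_sizes[0]] if self.layer_sizes else []
        for p in self.layers:
            if p.d != dims[-1]:
                raise ValueError(
                    f"layer input dim {p.d} does not match previous output {dims[-1]}"
                )
            dims.append(p.d_hidden)
        if self.layer_sizes and dims != list(self.layer_sizes):
            raise ValueError(f"layer_sizes {self.layer_sizes} inconsistent with layers {dims}")

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def output_dim(self) -> int:
        return self.layer_sizes[-1]


def pretrain_stack(X: np.ndarray, layer_sizes: list, cfg: DaeTrainConfig) -> StackedEncoder:
    """Greedy layer-wise pretraining.

    Layer 1 trains on X; its (uncorrupted) codes become the training set
    for layer 2, and so on.  Corruption applies to each layer's own input.
    ``layer_sizes == [d]`` yields an empty stack whose transform is the
    identity.  Labels are never seen here — pretraining is unsupervised.
    """
    X = np.asarray(X, dtype=float)
    if layer_sizes[0] != X.shape[1]:
        raise ValueError(
            f"layer_sizes[0] = {layer_sizes[0]} but data has {X.shape[1]} columns"
        )
    seeds = np.random.SeedSequence(cfg.seed).spawn(max(1, len(layer_sizes) - 1))
    layers, traces = [], []
    current = X
    for k in range(1, len(layer_sizes)):
        layer_cfg = DaeTrainConfig(
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            loss_kind=cfg.loss_kind,
            v=cfg.v,
            seed=int(seeds[k - 1].generate_state(1)[0] % (2**31)),
        )
        p, trace = train_dae(current, layer_cfg, layer_sizes[k])
        layers.append(p)
        traces.append(trace)
        current = encode(p, current)
    return StackedEncoder(layers=layers, layer_sizes=list(layer_sizes), loss_traces=traces)


def transform(se: StackedEncoder, X: np.ndarray) -> np.ndarray:
    """Sequential encode through every layer; no corruption at transform time."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != se.layer_sizes[0]:
        raise ValueError(
            f"input has {X.shape[-1]} columns, stack expects {se.layer_sizes[0]}"
        )
    for p in se.layers:
        X = encode(p, X)
    return X
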