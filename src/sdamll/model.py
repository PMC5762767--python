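"""The composed SdaMLL model: unsupervised stacked-DAE pretraining, then
BP-MLL on the codes.

The two stages are strictly sequential: pretraining sees only the feature
matrix (the API passes no labels into it), and the encoder is frozen once
pretrained — BP-MLL trains on the fixed codes, with no supervised
fine-tuning of the encoder weights.  With ``layer_sizes=[d]`` the stack is
empty and the model degenerates to plain BP-MLL on the raw features, which
is exactly how the BP-MLL baseline is obtained.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import autoencoder as ae
from . import bpmll
from .datamodel import MultiLabelDataset, RankedPrediction

__all__ = ["SdamllConfig", "SdamllModel", "default_layer_sizes", "fit", "predict",
           "save_model", "load_model"]


def default_layer_sizes(d: int) -> list:
    """Single code layer: 200 units when d > 200 (the reference shape —
    reduce from ~19k terms to a 200-dimensional code), else ⌈d/2⌉."""
    code = 200 if d > 200 else max(1, math.ceil(d / 2))
    return [d, code]


@dataclass
class SdamllConfig:
    layer_sizes: list | None = None  # None -> default_layer_sizes(d)
    dae: ae.DaeTrainConfig = field(default_factory=ae.DaeTrainConfig)
    bpmll: bpmll.BpmllTrainConfig = field(default_factory=bpmll.BpmllTrainConfig)

    def resolved_layer_sizes(self, d: int) -> list:
        if self.layer_sizes is None:
            return default_layer_sizes(d)
        if self.layer_sizes[0] != d:
            raise ValueError(
                f"layer_sizes[0] = {self.layer_sizes[0]} but data has {d} features"
            )
        return list(self.layer_sizes)

    def to_dict(self) -> dict:
        return {
            "layer_sizes": self.layer_sizes,
            "dae": vars(self.dae).copy(),
            "bpmll": vars(self.bpmll).copy(),
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "SdamllConfig":
        return cls(
            layer_sizes=cfg.get("layer_sizes"),
            dae=ae.DaeTrainConfig(**cfg.get("dae", {})),
            bpmll=bpmll.BpmllTrainConfig(**cfg.get("bpmll", {})),
        )


@dataclass
class SdamllModel:
    encoder: ae.StackedEncoder
    classifier: bpmll.BpmllNetwork
    config: dict
    label_names: list
    bpmll_trace: list
    dae_traces: list

    def __post_init__(self):
        if self.encoder.output_dim != self.classifier.d:
            raise ValueError(
                f"encoder emits {self.encoder.output_dim}-dim codes but the "
                f"classifier expects {self.classifier.d}"
            )


def fit(ds: MultiLabelDataset, cfg: SdamllConfig | None = None) -> SdamllModel:
    """Pretrain the stack on features alone, transform, train BP-MLL on codes."""
    if cfg is None:
        cfg = SdamllConfig()
    layer_sizes = cfg.resolved_layer_sizes(ds.n_features)
    encoder = ae.pretrain_stack(ds.features, layer_sizes, cfg.dae)
    codes = ae.transform(encoder, ds.features)
    code_ds = ds.with_features(codes)
    classifier, trace = bpmll.train_bpmll(code_ds, cfg.bpmll)
    return SdamllModel(
        encoder=encoder,
        classifier=classifier,
        config=cfg.to_dict() | {"layer_sizes": layer_sizes},
        label_names=list(ds.label_names),
        bpmll_trace=trace,
        dae_traces=encoder.loss_traces,
    )


def predict(model: SdamllModel, X: np.ndarray) -> RankedPrediction:
    """Scores = classifier outputs on the encoded rows."""
    codes = ae.transform(model.encoder, np.atleast_2d(np.asarray(X, dtype=float)))
    return bpmll.predict_scores(model.classifier, codes)


def save_model(model: SdamllModel, outdir: str) -> None:
    """Array archive (.npz) + JSON manifest, library-agnostic layout."""
    os.makedirs(outdir, exist_ok=True)
    arrays = {
        "classifier_V": model.classifier.V,
        "classifier_W": model.classifier.W,
        "classifier_hidden_bias": model.classifier.hidden_bias,
        "classifier_output_bias": model.classifier.output_bias,
    }
    for k, layer in enumerate(model.encoder.layers):
        arrays[f"encoder_{k}_W"] = layer.W
        arrays[f"encoder_{k}_b"] = layer.b
        arrays[f"encoder_{k}_b_prime"] = layer.b_prime
    np.savez(os.path.join(outdir, "arrays.npz"), **arrays)
    manifest = {
        "format": "sdamll-model-v1",
        "layer_sizes": [int(s) for s in model.encoder.layer_sizes],
        "label_names": model.label_names,
        "config": model.config,
        "bpmll_trace": [float(e) for e in model.bpmll_trace],
        "dae_traces": [[float(e) for e in t] for t in model.dae_traces],
    }
    with open(os.path.join(outdir, "model.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(outdir: str) -> SdamllModel:
    with open(os.path.join(outdir, "model.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "sdamll-model-v1":
        raise ValueError(f"unrecognized model format in {outdir}")
    arrays = np.load(os.path.join(outdir, "arrays.npz"))
    layer_sizes = manifest["layer_sizes"]
    layers = [
        ae.DenoisingAutoencoderParams(
            W=arrays[f"encoder_{k}_W"],
            b=arrays[f"encoder_{k}_b"],
            b_prime=arrays[f"encoder_{k}_b_prime"],
        )
        for k in range(len(layer_sizes) - 1)
    ]
    encoder = ae.StackedEncoder(
        layers=layers,
        layer_sizes=layer_sizes,
        loss_traces=manifest.get("dae_traces", []),
    )
    classifier = bpmll.BpmllNetwork(
        V=arrays["classifier_V"],
        W=arrays["classifier_W"],
        hidden_bias=arrays["classifier_hidden_bias"],
        output_bias=arrays["classifier_output_bias"],
    )
    return SdamllModel(
        encoder=encoder,
        classifier=classifier,
        config=manifest["config"],
        label_names=manifest["label_names"],
        bpmll_trace=manifest.get("bpmll_trace", []),
        dae_traces=manifest.get("dae_traces", []),
    )
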