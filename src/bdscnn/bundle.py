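"""Weight-bundle serialization: JSON header plus base64-packed bitmasks.

Binary weight tensors are bit-packed (np.packbits) and base64-encoded; BN
parameters are stored as JSON decimals (Python round-trips float64 exactly
through repr), so a save/load cycle is bit-exact and a reloaded model
classifies identically.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .model import BNParams, ModelWeights

__all__ = ["save_weights", "load_weights"]

_FORMAT = "bdscnn-bundle-v1"


def _pack(arr: np.ndarray) -> dict:
    return {
        "shape": list(arr.shape),
        "bits": base64.b64encode(np.packbits(arr.reshape(-1))).decode("ascii"),
    }


def _unpack(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    n = int(np.prod(shape))
    raw = np.frombuffer(base64.b64decode(d["bits"]), dtype=np.uint8)
    return np.unpackbits(raw)[:n].reshape(shape).astype(np.uint8)


def _bn_to_json(p: BNParams) -> dict:
    return {"gamma": p.gamma.tolist(), "beta": p.beta.tolist(),
            "mu": p.mu.tolist(), "sigma": p.sigma.tolist(), "eps": p.eps}


def _bn_from_json(d: dict) -> BNParams:
    return BNParams(gamma=np.array(d["gamma"]), beta=np.array(d["beta"]),
                    mu=np.array(d["mu"]), sigma=np.array(d["sigma"]),
                    eps=d["eps"])


def save_weights(w: ModelWeights, path, meta: dict | None = None) -> None:
    doc = {
        "format": _FORMAT,
        "config": w.config.to_dict(),
        "weights": {name: _pack(getattr(w, name))
                    for name in ("conv1", "dw", "pw", "fc1", "fc2")},
        "bn": {name: _bn_to_json(getattr(w, name))
               for name in ("bn_dsc", "bn_fc1", "bn_fc2")},
        "meta": meta or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_weights(path) -> ModelWeights:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != _FORMAT:
        raise ValueError(f"not a {_FORMAT} file: {path}")
    cfg = ModelConfig.from_dict(doc["config"])
    return ModelWeights(
        conv1=_unpack(doc["weights"]["conv1"]),
        dw=_unpack(doc["weights"]["dw"]),
        pw=_unpack(doc["weights"]["pw"]),
        fc1=_unpack(doc["weights"]["fc1"]),
        fc2=_unpack(doc["weights"]["fc2"]),
        bn_dsc=_bn_from_json(doc["bn"]["bn_dsc"]),
        bn_fc1=_bn_from_json(doc["bn"]["bn_fc1"]),
        bn_fc2=_bn_from_json(doc["bn"]["bn_fc2"]),
        config=cfg,
    )
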