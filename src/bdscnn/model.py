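"""Reference forward path of the binarized depthwise-separable CNN.

All weights and activations are {0,1} bits, so every "multiplication" is a
logical AND and every dot product a popcount.  The layer order is:

    conv1 (valid, binary) -> binarize(>0) -> 2x2 OR-max-pool
    -> depthwise 3x3 (integer popcounts, NOT binarized)
    -> pointwise 1x1 (channel mix) -> batch-norm -> binarize
    -> flatten + RR code -> FC1 popcount -> BN -> binarize
    -> FC2 popcount -> BN -> softmax (training/reference only)

The first-layer activation threshold is exactly 0 (no batch norm after
conv1); this is what makes the merged convolution-pooling algebra exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG

__all__ = [
    "BNParams",
    "ModelWeights",
    "binarize",
    "bconv_valid",
    "or_maxpool",
    "dsc_forward",
    "flatten_dsc",
    "forward",
    "random_weights",
    "count_params_and_ops",
]


@dataclass
class BNParams:
    """Per-unit batch-norm parameters: y = gamma*(x - mu)/sqrt(sigma^2+eps) + beta."""

    gamma: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray  # standard deviation, not variance
    eps: float = 1e-4

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=np.float64))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Normalize x along its last axis (one BN unit per channel)."""
        return self.gamma * (x - self.mu) / np.sqrt(self.sigma**2 + self.eps) + self.beta

    def __len__(self) -> int:
        return self.gamma.shape[0]


@dataclass
class ModelWeights:
    """All binarized weights plus BN parameters for one trained model.

    Every weight array holds {0,1} values (uint8).  Shapes follow the
    configuration: conv1 (K,KO,KO), dw (K,KD,KD), pw (KP,K),
    fc1 (fc1_in,F1), fc2 (F1,C).
    """

    conv1: np.ndarray
    dw: np.ndarray
    pw: np.ndarray
    bn_dsc: BNParams
    fc1: np.ndarray
    bn_fc1: BNParams
    fc2: np.ndarray
    bn_fc2: BNParams
    config: ModelConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self):
        cfg = self.config
        for name in ("conv1", "dw", "pw", "fc1", "fc2"):
            arr = np.asarray(getattr(self, name))
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0/1")
            setattr(self, name, arr.astype(np.uint8))
        expected = {
            "conv1": (cfg.K, cfg.KO, cfg.KO),
            "dw": (cfg.K, cfg.KD, cfg.KD),
            "pw": (cfg.KP, cfg.K),
            "fc1": (cfg.fc1_in, cfg.F1),
            "fc2": (cfg.F1, cfg.C),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        for bn, n in (("bn_dsc", cfg.KP), ("bn_fc1", cfg.F1), ("bn_fc2", cfg.C)):
            if len(getattr(self, bn)) != n:
                raise ValueError(f"{bn} must have {n} channels")


def binarize(x):
    """0,1 binarization: 1 if x > 0 else 0.  Applied to weights and activations."""
    return (np.asarray(x) > 0).astype(np.uint8)


def bconv_valid(image: np.ndarray, kernel: np.ndarray, stride: int = 1) -> np.ndarray:
    """Valid binary convolution: popcount of (window AND kernel) at each position.

    `image` and `kernel` are {0,1} grids; the output holds small nonnegative
    integers (at most kernel.sum()).
    """
    image = np.asarray(image)
    kernel = np.asarray(kernel)
    kh, kw = kernel.shape
    if image.shape[0] < kh or image.shape[1] < kw:
        raise ValueError("kernel larger than image")
    win = np.lib.stride_tricks.sliding_window_view(image, (kh, kw))[::stride, ::stride]
    return np.einsum("xyab,ab->xy", win.astype(np.int64), kernel.astype(np.int64))


def or_maxpool(bits: np.ndarray, P: int = 2, SP: int = 2) -> np.ndarray:
    """Max-pool of a {0,1} grid == OR over each PxP window, stride SP."""
    bits = np.asarray(bits)
    if bits.shape[0] < P or bits.shape[1] < P:
        raise ValueError("grid smaller than pool window")
    win = np.lib.stride_tricks.sliding_window_view(bits, (P, P))[::SP, ::SP]
    return win.max(axis=(2, 3)).astype(np.uint8)


def dsc_forward(
    maps: np.ndarray,
    dw: np.ndarray,
    pw: np.ndarray,
    bn: BNParams,
    return_presum: bool = False,
):
    """Depthwise-separable layer on K binary maps.

    maps: (side, side, K) bits.  Per channel c the depthwise 3x3 popcount grid
    is kept as integers (the hardware carries them at 4-bit width); the
    pointwise step mixes channels with binary weights, then batch-norm and
    binarization produce KP binary output maps.
    """
    maps = np.asarray(maps)
    K = maps.shape[2]
    if dw.shape[0] != K or pw.shape[1] != K:
        raise ValueError("channel count mismatch between maps and kernels")
    kd = dw.shape[1]
    if maps.shape[0] < kd:
        raise ValueError("map smaller than depthwise kernel")
    win = np.lib.stride_tricks.sliding_window_view(maps, (kd, kd), axis=(0, 1))
    # win: (side-kd+1, side-kd+1, K, kd, kd)
    dw_out = np.einsum("xykab,kab->xyk", win.astype(np.int64), dw.astype(np.int64))
    pw_sum = np.einsum("xyk,pk->xyp", dw_out, pw.astype(np.int64))
    out = binarize(bn.apply(pw_sum.astype(np.float64)))
    if return_presum:
        return out, pw_sum
    return out


def flatten_dsc(maps: np.ndarray) -> np.ndarray:
    """Flatten a (MD, MD, KP) feature map in (row, col, channel) order.

    Index of (i, j, p) is (i*MD + j)*KP + p — the same ownership order the
    blockwise engine uses for FC1 weight rows.
    """
    return np.asarray(maps).reshape(-1)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def forward(image: np.ndarray, rr_code: Sequence[int], w: ModelWeights):
    """Full reference forward pass for one beat.

    Returns (softmax scores over the C classes, argmax label index).  Pure
    function of its inputs; ties in the argmax break toward the lowest class
    index (N < S < V < F < Q).
    """
    cfg = w.config
    image = np.asarray(image)
    if image.shape != (cfg.M, cfg.M):
        raise ValueError(f"image must be {cfg.M}x{cfg.M}")
    rr_code = np.asarray(rr_code).reshape(-1)
    if rr_code.shape[0] != cfg.rr_bits:
        raise ValueError(f"rr_code must have {cfg.rr_bits} bits")

    pooled = np.stack(
        [
            or_maxpool(binarize(bconv_valid(image, w.conv1[k], cfg.SO)), cfg.P, cfg.SP)
            for k in range(cfg.K)
        ],
        axis=2,
    )
    feat = dsc_forward(pooled, w.dw, w.pw, w.bn_dsc)
    z = np.concatenate([flatten_dsc(feat), binarize(rr_code)]).astype(np.int64)
    fc1_pre = z @ w.fc1.astype(np.int64)
    a1 = binarize(w.bn_fc1.apply(fc1_pre.astype(np.float64)))
    fc2_pre = a1.astype(np.int64) @ w.fc2.astype(np.int64)
    scores_raw = w.bn_fc2.apply(fc2_pre.astype(np.float64))
    scores = _softmax(scores_raw)
    return scores, int(np.argmax(scores_raw))


def random_weights(cfg: ModelConfig = DEFAULT_CONFIG, seed: int = 0) -> ModelWeights:
    """Random {0,1} weights with random but well-conditioned BN parameters.

    Used by equivalence and property tests; BN means are centered near the
    expected popcount scale of each layer so that activations are not
    saturated."""
    rng = np.random.default_rng(seed)

    def bn(n: int, scale: float) -> BNParams:
        return BNParams(
            gamma=rng.uniform(0.5, 1.5, n),
            beta=rng.normal(0.0, 1.0, n),
            mu=rng.uniform(0.25, 0.75, n) * scale,
            sigma=rng.uniform(0.5, 1.5, n) * max(scale / 4.0, 1.0),
            eps=1e-4,
        )

    cfg.validate()
    return ModelWeights(
        conv1=rng.integers(0, 2, (cfg.K, cfg.KO, cfg.KO)),
        dw=rng.integers(0, 2, (cfg.K, cfg.KD, cfg.KD)),
        pw=rng.integers(0, 2, (cfg.KP, cfg.K)),
        bn_dsc=bn(cfg.KP, cfg.KD**2 * cfg.K / 4.0),
        fc1=rng.integers(0, 2, (cfg.fc1_in, cfg.F1)),
        bn_fc1=bn(cfg.F1, cfg.fc1_in / 4.0),
        fc2=rng.integers(0, 2, (cfg.F1, cfg.C)),
        bn_fc2=bn(cfg.C, cfg.F1 / 4.0),
        config=cfg,
    )


def count_params_and_ops(cfg: ModelConfig = DEFAULT_CONFIG, second_layer: str = "dsc") -> dict:
    """Parameter and convolutional-operation counts for the second layer.

    A depthwise-separable second layer needs KD^2 per input channel plus one
    pointwise weight per (input, output) channel pair: KD^2*K + K*KP
    parameters, against KD^2*K*KP for a conventional convolution — a factor
    (KD^2*N)/(KD^2+N) reduction (6x at KD=3, N=18).  Operation counts are per
    output position: Coperation(dsc) = MD^2*K*KD^2 + MD^2*KP*K,
    Coperation(conventional) = MD^2*KP*KD^2*K.
    """
    if second_layer not in ("dsc", "conventional"):
        raise ValueError("second_layer must be 'dsc' or 'conventional'")
    cfg.validate()
    md2 = cfg.MD**2
    if second_layer == "dsc":
        second_params = cfg.KD**2 * cfg.K + cfg.K * cfg.KP
        coperation = md2 * cfg.K * cfg.KD**2 + md2 * cfg.KP * cfg.K
        kernel_count = cfg.K + cfg.K + cfg.KP  # conv1 + dw + pw
    else:
        second_params = cfg.KD**2 * cfg.K * cfg.KP
        coperation = md2 * cfg.KP * cfg.KD**2 * cfg.K
        kernel_count = cfg.K + cfg.KP
    conv1_params = cfg.K * cfg.KO**2
    return {
        "second_layer": second_layer,
        "kernel_count": kernel_count,
        "conv1_params": conv1_params,
        "second_layer_params": second_params,
        "kernel_params": conv1_params + second_params,
        "coperation": coperation,
    }
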