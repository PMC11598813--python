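"""Batch-norm folding and the integer-only inference twin.

After training, every BN-then-binarize pair is collapsed into an integer
comparator: since the pre-activation s is an integer popcount and the
composite activation fires iff gamma*(s-mu)/sqrt(sigma^2+eps) + beta > 0,
for gamma > 0 that is exactly

    s > floor(mu - beta*sqrt(sigma^2+eps)/gamma),

so a single integer threshold per channel replaces the whole BN layer.  For
gamma < 0 the inequality direction flips (s < t, encoded as s <= ceil(t)-1)
and the channel is flagged.  The FC2 BN has no binarization after it, so it
is realized as a per-class lookup table indexed by the FC2 popcount; the
classification is the argmax of the looked-up values.

The lookup table is kept at two precisions: exact (float64, used for
classification, guaranteeing argmax agreement with the reference forward
pass) and a 13-bit signed fixed-point view with 6 fractional bits mirroring
the hardware registers.  Folding reports whether the quantized view
preserves every cross-class ordering; when it does, the hardware twin is
certified bit-equivalent as a classifier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .model import BNParams, ModelWeights, binarize, flatten_dsc
from .mcp import MCPKernel, build_mcpk, mcp_apply

__all__ = [
    "bn_threshold_real",
    "fold_bn_threshold",
    "fold_bn_thresholds",
    "build_fc2_lut",
    "FoldedModel",
    "fold_model",
    "integer_forward",
    "evaluate_model",
]

FC2_LUT_TOTAL_BITS = 13
FC2_LUT_FRAC_BITS = 6


def bn_threshold_real(p: BNParams) -> np.ndarray:
    """Pre-floor comparator bound mu - beta*sqrt(sigma^2+eps)/gamma, per channel."""
    if np.any(p.gamma == 0):
        raise ValueError("gamma = 0: batch norm is constant, fold is non-invertible")
    return p.mu - p.beta * np.sqrt(p.sigma**2 + p.eps) / p.gamma


def fold_bn_threshold(p: BNParams) -> int:
    """Integer comparator threshold for a single-channel BN (gamma > 0).

    The activation fires iff the integer pre-activation exceeds the floored
    bound; flooring is exact because s > t  <=>  s > floor(t) for integer s.
    """
    t = bn_threshold_real(p)
    if t.shape[0] != 1:
        raise ValueError("fold_bn_threshold is per-channel; use fold_bn_thresholds")
    if p.gamma[0] < 0:
        raise ValueError("gamma < 0 flips the comparison; use fold_bn_thresholds")
    return int(math.floor(t[0]))


def fold_bn_thresholds(p: BNParams) -> tuple[np.ndarray, np.ndarray]:
    """Vector fold: (thresholds, flipped flags).

    Un-flipped channels fire iff s > threshold (threshold = floor(bound));
    flipped channels (gamma < 0) fire iff s <= threshold
    (threshold = ceil(bound) - 1, so that s <= threshold <=> s < bound).
    """
    t = bn_threshold_real(p)
    flipped = p.gamma < 0
    thr = np.where(flipped, np.ceil(t) - 1, np.floor(t)).astype(np.int64)
    if flipped.any():
        warnings.warn(
            f"{int(flipped.sum())} BN channel(s) folded with negative gamma; "
            "comparator direction flipped"
        )
    return thr, flipped


def _fire(s: np.ndarray, thr: np.ndarray, flipped: np.ndarray) -> np.ndarray:
    return np.where(flipped, s <= thr, s > thr).astype(np.uint8)


def build_fc2_lut(p: BNParams, max_sum: int, channel: int = 0,
                  frac_bits: int = FC2_LUT_FRAC_BITS,
                  total_bits: int = FC2_LUT_TOTAL_BITS) -> np.ndarray:
    """Fixed-point BN lookup table for one output class.

    entry[s] = BN(s) quantized to signed `total_bits` fixed point with
    `frac_bits` fractional bits, for s = 0..max_sum.  Raises if any entry
    leaves the representable range.
    """
    if max_sum < 1:
        raise ValueError("max_sum must be >= 1")
    s = np.arange(max_sum + 1, dtype=np.float64)
    exact = (p.gamma[channel] * (s - p.mu[channel])
             / np.sqrt(p.sigma[channel] ** 2 + p.eps) + p.beta[channel])
    scale = 1 << frac_bits
    codes = np.rint(exact * scale)
    limit = (1 << (total_bits - 1)) - 1
    if np.any(np.abs(codes) > limit):
        bad = int(np.argmax(np.abs(codes) > limit))
        raise OverflowError(
            f"LUT entry {bad} (value {exact[bad]:.4f}) exceeds the "
            f"{total_bits}-bit fixed-point range"
        )
    return codes / scale


@dataclass
class FoldedModel:
    """Integer-threshold twin of a trained model (Fig-9-style datapath)."""

    mcpks: list  # K MCPKernels
    dw: np.ndarray
    pw: np.ndarray
    pw_thresholds: np.ndarray
    pw_flipped: np.ndarray
    fc1: np.ndarray
    fc1_thresholds: np.ndarray
    fc1_flipped: np.ndarray
    fc2: np.ndarray
    fc2_lut_exact: np.ndarray   # (C, F1+1) float64, classification path
    fc2_lut_q13: np.ndarray     # (C, F1+1) 13-bit/6-frac quantized view
    config: ModelConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    @property
    def quantization_order_safe(self) -> bool:
        """True if the 13-bit LUT preserves every cross-class ordering of the
        exact LUT (then the hardware-width twin classifies identically)."""
        ex, q = self.fc2_lut_exact, self.fc2_lut_q13
        C = ex.shape[0]
        for a in range(C):
            for b in range(a + 1, C):
                d_ex = ex[a][:, None] - ex[b][None, :]
                d_q = q[a][:, None] - q[b][None, :]
                if np.any((d_ex > 0) & (d_q < 0)) or np.any((d_ex < 0) & (d_q > 0)):
                    return False
        return True


def fold_model(w: ModelWeights) -> FoldedModel:
    cfg = w.config
    pw_thr, pw_fl = fold_bn_thresholds(w.bn_dsc)
    fc1_thr, fc1_fl = fold_bn_thresholds(w.bn_fc1)
    # Exact LUT: the same float64 expression the reference BN evaluates, so
    # the looked-up values are bit-identical to the reference forward pass.
    s = np.arange(cfg.F1 + 1, dtype=np.float64)
    p = w.bn_fc2
    lut_exact = np.stack(
        [p.gamma[c] * (s - p.mu[c]) / np.sqrt(p.sigma[c] ** 2 + p.eps) + p.beta[c]
         for c in range(cfg.C)]
    )
    lut_q = np.stack(
        [build_fc2_lut(w.bn_fc2, cfg.F1, c) for c in range(cfg.C)]
    )
    return FoldedModel(
        mcpks=[build_mcpk(w.conv1[k], cfg.SO, cfg.P, cfg.SP) for k in range(cfg.K)],
        dw=w.dw.copy(),
        pw=w.pw.copy(),
        pw_thresholds=pw_thr,
        pw_flipped=pw_fl,
        fc1=w.fc1.copy(),
        fc1_thresholds=fc1_thr,
        fc1_flipped=fc1_fl,
        fc2=w.fc2.copy(),
        fc2_lut_exact=lut_exact,
        fc2_lut_q13=lut_q,
        config=cfg,
    )


def _feature_bits(image: np.ndarray, fm: FoldedModel) -> np.ndarray:
    """Layerwise MCP -> DW -> PW+threshold, returning (MD, MD, KP) bits."""
    cfg = fm.config
    mcp_maps = np.stack([mcp_apply(image, mk) for mk in fm.mcpks], axis=2)
    win = np.lib.stride_tricks.sliding_window_view(
        mcp_maps, (cfg.KD, cfg.KD), axis=(0, 1)
    )
    dw_out = np.einsum("xykab,kab->xyk", win.astype(np.int64), fm.dw.astype(np.int64))
    pw_sum = np.einsum("xyk,pk->xyp", dw_out, fm.pw.astype(np.int64))
    return _fire(pw_sum, fm.pw_thresholds, fm.pw_flipped)


def integer_forward(image: np.ndarray, rr_code, fm: FoldedModel,
                    engine: str = "layerwise", strict: bool = False,
                    hardware_lut: bool = False):
    """Integer-only forward pass: AND/popcount/compare/lookup, nothing else.

    Returns (one-hot vector of length C, looked-up class values).  With
    `engine="blockwise"` the FC1 pre-activations come from the incremental
    block engine (bit-identical by construction).  `strict` checks the
    hardware register widths (4-bit DW, 12-bit FC1, 5-bit FC2 sums) and
    raises on overflow; `hardware_lut` classifies from the 13-bit quantized
    table instead of the exact one.
    """
    cfg = fm.config
    image = binarize(image)
    rr = binarize(np.asarray(rr_code).reshape(-1))
    if rr.shape[0] != cfg.rr_bits:
        raise ValueError(f"rr_code must have {cfg.rr_bits} bits")

    if engine == "blockwise":
        from .blockwise import blockwise_fc1

        fc1_pre = blockwise_fc1(image, rr, fm, strict_widths=strict)
    elif engine == "layerwise":
        feat = _feature_bits(image, fm)
        z = np.concatenate([flatten_dsc(feat), rr]).astype(np.int64)
        fc1_pre = z @ fm.fc1.astype(np.int64)
    else:
        raise ValueError("engine must be 'layerwise' or 'blockwise'")

    if strict and np.any(np.abs(fc1_pre) > 2047):
        raise OverflowError("FC1 pre-activation exceeds the 12-bit register range")
    a1 = _fire(fc1_pre, fm.fc1_thresholds, fm.fc1_flipped)
    fc2_sum = a1.astype(np.int64) @ fm.fc2.astype(np.int64)
    if strict and np.any(fc2_sum > 31):
        raise OverflowError("FC2 popcount exceeds the 5-bit register range")
    lut = fm.fc2_lut_q13 if hardware_lut else fm.fc2_lut_exact
    values = lut[np.arange(cfg.C), fc2_sum]
    label = int(np.argmax(values))  # np.argmax ties -> lowest index
    onehot = np.zeros(cfg.C, dtype=np.uint8)
    onehot[label] = 1
    return onehot, values


def evaluate_model(test_set, fm: FoldedModel, engine: str = "layerwise"):
    """Classify every (image, rr_code, label) item and aggregate a confusion
    matrix (rows = predicted, columns = original) plus the metric report."""
    from .metrics import ConfusionMatrix5, metric_report

    items = list(test_set)
    if not items:
        raise ValueError("empty test set")
    counts = np.zeros((fm.config.C, fm.config.C), dtype=np.int64)
    for image, rr_code, label in items:
        onehot, _ = integer_forward(image, rr_code, fm, engine=engine)
        counts[int(np.argmax(onehot)), int(label)] += 1
    cm = ConfusionMatrix5(counts)
    return cm, metric_report(cm)
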