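"""Blockwise incremental inference and the latency/storage cost models.

Instead of materializing every intermediate feature map, the input image is
cut into MD x MD overlapping blocks (8x8 with the default geometry, origin
stepping by SR).  Each block runs MCP -> depthwise -> pointwise+threshold ->
partial FC1 on its own, contributing to the F1 running accumulators; after
all blocks the accumulators equal the layerwise FC1 pre-activations exactly,
because integer accumulation is order-independent.  The engine therefore
trades recomputation of overlapping pixels for storage: per stage it holds
only {block, 3x3xK, 1x1xK, 1x1xKP, F1} values instead of whole maps.

Latency is modeled in the one-operation-per-cycle convention:
layerwise  L  = MC^2 + 2*MD^2 + KP*MD^2,
blockwise  LB = (KD^2 + 1 + 1 + KP) * MD^2,
pipelined  LB = KP * MD^2  (feature extraction hidden behind FC1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .mcp import MCPKernel, build_mcpk, mcp_apply

__all__ = [
    "LatencyReport",
    "extract_block",
    "process_block",
    "blockwise_fc1",
    "latency_report",
    "storage_report",
]


@dataclass(frozen=True)
class LatencyReport:
    MC: int
    MD: int
    n_blocks: int
    L: int
    LB: int
    LB_pipelined: int

    def to_dict(self) -> dict:
        return {
            "MC": self.MC,
            "MD": self.MD,
            "n_blocks": self.n_blocks,
            "L": self.L,
            "LB": self.LB,
            "LB_pipelined": self.LB_pipelined,
        }


def extract_block(image: np.ndarray, i: int, j: int,
                  cfg: ModelConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The (i, j)-th overlapping input block (8x8 by default, origin (SR*i, SR*j))."""
    image = np.asarray(image)
    if not (0 <= i < cfg.MD and 0 <= j < cfg.MD):
        raise IndexError(f"block index ({i}, {j}) outside 0..{cfg.MD - 1}")
    b = cfg.block_side
    r0, c0 = cfg.SR * i, cfg.SR * j
    return image[r0 : r0 + b, c0 : c0 + b]


def _mcpks(w) -> list[MCPKernel]:
    cfg = w.config
    return [build_mcpk(w.conv1[k], cfg.SO, cfg.P, cfg.SP) for k in range(cfg.K)]


def _pw_thresholds(w) -> np.ndarray:
    # Lazy import: fold owns Eq-10 threshold folding.
    from .fold import fold_bn_thresholds

    thr, flipped = fold_bn_thresholds(w.bn_dsc)
    if flipped.any():
        raise ValueError("negative-gamma BN channel: use a FoldedModel explicitly")
    return thr


def process_block(block: np.ndarray, w, i: int, j: int,
                  mcpks: list[MCPKernel] | None = None,
                  pw_thresholds: np.ndarray | None = None) -> np.ndarray:
    """Run one block through MCP -> DW -> PW+threshold -> partial FC1.

    Returns the F1 partial sums contributed by the KP feature bits this block
    owns (FC1 weight rows (i*MD + j)*KP ... +KP).  Accepts either raw
    ModelWeights (thresholds folded on the fly) or precomputed kernels and
    thresholds.
    """
    cfg = w.config
    block = np.asarray(block)
    if block.shape != (cfg.block_side, cfg.block_side):
        raise ValueError(f"block must be {cfg.block_side}x{cfg.block_side}")
    if mcpks is None:
        mcpks = getattr(w, "mcpks", None) or _mcpks(w)
    if pw_thresholds is None:
        pw_thresholds = getattr(w, "pw_thresholds", None)
        if pw_thresholds is None:
            pw_thresholds = _pw_thresholds(w)

    # MCP: KD x KD x K bits from the block.
    mcp_bits = np.stack([mcp_apply(block, mk) for mk in mcpks], axis=2)
    # Depthwise collapses the KD x KD window to one popcount per channel.
    dw_out = np.einsum(
        "abk,kab->k", mcp_bits.astype(np.int64), w.dw.astype(np.int64)
    )
    pw_sum = w.pw.astype(np.int64) @ dw_out
    feat_bits = (pw_sum > pw_thresholds).astype(np.int64)
    row0 = (i * cfg.MD + j) * cfg.KP
    return feat_bits @ w.fc1[row0 : row0 + cfg.KP].astype(np.int64)


def blockwise_fc1(image: np.ndarray, rr_code, w,
                  strict_widths: bool = False) -> np.ndarray:
    """FC1 pre-activations by blockwise incremental accumulation.

    Bit-exactly equal to the layerwise FC1 pre-activations for any weights
    and image.  With strict_widths the accumulators are checked against the
    12-bit signed register range of the hardware datapath.
    """
    cfg = w.config
    image = np.asarray(image)
    if image.shape != (cfg.M, cfg.M):
        raise ValueError(f"image must be {cfg.M}x{cfg.M}")
    mcpks = getattr(w, "mcpks", None) or _mcpks(w)
    pw_thr = getattr(w, "pw_thresholds", None)
    if pw_thr is None:
        pw_thr = _pw_thresholds(w)
    acc = np.zeros(cfg.F1, dtype=np.int64)
    for i in range(cfg.MD):
        for j in range(cfg.MD):
            acc += process_block(extract_block(image, i, j, cfg), w, i, j,
                                 mcpks=mcpks, pw_thresholds=pw_thr)
            if strict_widths and np.any(np.abs(acc) > 2047):
                raise OverflowError(
                    f"FC1 accumulator exceeded the 12-bit range after block ({i},{j})"
                )
    rr = np.asarray(rr_code).reshape(-1).astype(np.int64)
    acc += rr @ w.fc1[cfg.MD * cfg.MD * cfg.KP :].astype(np.int64)
    return acc


def latency_report(cfg: ModelConfig = DEFAULT_CONFIG) -> LatencyReport:
    """Cycle counts of the three execution schedules (model cycles, not wall clock)."""
    cfg.validate()
    mc, md = cfg.MC, cfg.MD
    md2 = md * md
    return LatencyReport(
        MC=mc,
        MD=md,
        n_blocks=md2,
        L=mc**2 + 2 * md2 + cfg.KP * md2,
        LB=(cfg.KD**2 + 1 + 1 + cfg.KP) * md2,
        LB_pipelined=cfg.KP * md2,
    )


def storage_report(cfg: ModelConfig = DEFAULT_CONFIG) -> dict:
    """Intermediate-value storage per stage, layerwise vs blockwise."""
    cfg.validate()
    layerwise = {
        "input": cfg.M**2,
        "mcp": cfg.MC**2 * cfg.K,
        "dw": cfg.MD**2 * cfg.K,
        "pw": cfg.MD**2 * cfg.KP,
        "fc1_in": cfg.MD**2 * cfg.KP,
    }
    blockwise = {
        "input": cfg.block_side**2,
        "mcp": cfg.KD**2 * cfg.K,
        "dw": cfg.K,
        "pw": cfg.KP,
        "fc1_in": cfg.KP,
    }
    lt, bt = sum(layerwise.values()), sum(blockwise.values())
    return {
        "layerwise": layerwise,
        "blockwise": blockwise,
        "layerwise_total": lt,
        "blockwise_total": bt,
        "ratio": lt / bt,
    }
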