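"""Merged convolution-pooling (MCP) kernel algebra.

For {0,1} data and weights with an activation threshold of exactly 0,

    binarize(popcount(window AND kernel)) = OR over (window AND kernel),

so conv -> binarize -> OR-max-pool collapses into a single pass with an
enlarged kernel built by OR-ing P^2 shifted copies of the original kernel:
bit (r, c) of the merged kernel is the OR of kernel[r - SO*dr][c - SO*dc]
over pool offsets (dr, dc) in {0..P-1}^2.  The merged kernel has side
KR = KO + SO*(P-1) and stride SR = SO*SP.  Zero bits can be pruned: they can
never affect an OR-reduction.

The algebra is only valid for a zero activation threshold; building an MCP
layer on top of a folded (nonzero-threshold) activation is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .model import binarize, bconv_valid, or_maxpool

__all__ = ["MCPKernel", "build_mcpk", "prune", "mcp_apply", "mcp_op_count"]


@dataclass
class MCPKernel:
    bits: np.ndarray        # (KR, KR) {0,1}
    stride: int             # SR = SO*SP
    source_kernel: np.ndarray
    SO: int
    P: int
    SP: int

    @property
    def side(self) -> int:
        return self.bits.shape[0]

    @property
    def nonzero_count(self) -> int:
        return int(self.bits.sum())

    def dump(self) -> str:
        """One row per line, 0/1 characters."""
        return "\n".join("".join(str(int(b)) for b in row) for row in self.bits)


def build_mcpk(kernel: np.ndarray, SO: int = 1, P: int = 2, SP: int = 2,
               activation_threshold: int = 0) -> MCPKernel:
    """OR-merge P^2 stride-SO shifted copies of `kernel` into one MCP kernel."""
    if activation_threshold != 0:
        raise ValueError(
            "MCP merging is only exact for a zero activation threshold; "
            "a popcount threshold > 0 does not commute with the OR-pool"
        )
    kernel = np.asarray(kernel)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError("kernel must be square")
    if min(kernel.shape[0], SO, P, SP) < 1:
        raise ValueError("KO, SO, P, SP must all be >= 1")
    KO = kernel.shape[0]
    KR = KO + SO * (P - 1)
    bits = np.zeros((KR, KR), dtype=np.uint8)
    kb = binarize(kernel)
    for dr in range(P):
        for dc in range(P):
            bits[SO * dr : SO * dr + KO, SO * dc : SO * dc + KO] |= kb
    return MCPKernel(bits=bits, stride=SO * SP, source_kernel=kb, SO=SO, P=P, SP=SP)


def prune(mcpk: MCPKernel) -> list[tuple[int, int]]:
    """Positions of the 1-bits; the only AND gates the OR-reduction needs."""
    rows, cols = np.nonzero(mcpk.bits)
    return list(zip(rows.tolist(), cols.tolist()))


def mcp_apply(image: np.ndarray, mcpk: MCPKernel, pruned: bool = False) -> np.ndarray:
    """One-pass merged conv-pool: OR of image bits under the kernel's 1-bits.

    Equals or_maxpool(binarize(bconv_valid(image, source, SO)), P, SP)
    bit-exactly (the module's core equivalence).
    """
    image = np.asarray(image)
    KR, SR = mcpk.side, mcpk.stride
    if image.shape[0] < KR or image.shape[1] < KR:
        raise ValueError("image smaller than MCP kernel")
    if pruned:
        side = (image.shape[0] - KR) // SR + 1
        out = np.zeros((side, (image.shape[1] - KR) // SR + 1), dtype=np.uint8)
        for (i, j) in prune(mcpk):
            out |= image[i : i + out.shape[0] * SR : SR,
                         j : j + out.shape[1] * SR : SR].astype(np.uint8)
        return out
    win = np.lib.stride_tricks.sliding_window_view(image, (KR, KR))[::SR, ::SR]
    return (win.astype(bool) & mcpk.bits.astype(bool)).any(axis=(2, 3)).astype(np.uint8)


def baseline_pipeline(image: np.ndarray, kernel: np.ndarray,
                      SO: int = 1, P: int = 2, SP: int = 2) -> np.ndarray:
    """The layerwise oracle the MCP pass must match: conv -> binarize -> pool."""
    return or_maxpool(binarize(bconv_valid(image, binarize(kernel), SO)), P, SP)


def mcp_op_count(cfg: ModelConfig = DEFAULT_CONFIG, pruned: bool = False,
                 kernels: list[MCPKernel] | None = None) -> dict:
    """First-layer operation counts: merged vs sequential conv+pool.

    Unpruned merged count = MC^2 * K * KR^2.  The sequential baseline costs
    KO^2 AND ops per conv output position plus 2 ops per 2x2 pool window
    (the convention under which the published 25,650 figure holds):
    conv1_side^2 * K * KO^2 + MC^2 * K * (P^2 - P).  With pruning the
    per-kernel cost is its nonzero count.
    """
    cfg.validate()
    mc2 = cfg.MC**2
    baseline = cfg.conv1_side**2 * cfg.K * cfg.KO**2 + mc2 * cfg.K * (cfg.P**2 - cfg.P)
    if pruned:
        if kernels is None:
            raise ValueError("pruned count needs the trained MCP kernels")
        merged = mc2 * sum(k.nonzero_count for k in kernels)
    else:
        merged = mc2 * cfg.K * cfg.KR**2
    return {"mcp_ops": merged, "baseline_ops": baseline, "pruned": pruned}
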