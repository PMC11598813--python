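"""Model geometry and derived sizes.

The default configuration is the published one: 32x32 binary beat images, a
3-channel 3x3 first convolution (stride 1) followed by a 2x2/stride-2
OR-max-pool, a depthwise-separable second layer (3x3 depthwise, 18 pointwise
channels), a 32-unit FC1 fed by the flattened 13x13x18 feature map plus a
4-bit RR-interval code, and a 5-class FC2 head.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ModelConfig:
    M: int = 32        # input image side, px
    K: int = 3         # first-layer channel count
    KO: int = 3        # first-layer kernel side
    SO: int = 1        # first-layer conv stride
    P: int = 2         # pool side
    SP: int = 2        # pool stride
    KD: int = 3        # depthwise kernel side
    KP: int = 18       # pointwise output channels
    F1: int = 32       # FC1 width
    C: int = 5         # classes
    rr_bits: int = 4   # RR-interval code width

    # -- merged-kernel geometry -------------------------------------------
    @property
    def KR(self) -> int:
        """Merged convolution-pooling kernel side: KO + SO*(P-1)."""
        return self.KO + self.SO * (self.P - 1)

    @property
    def SR(self) -> int:
        """Merged kernel stride: SO*SP."""
        return self.SO * self.SP

    # -- feature-map sides -------------------------------------------------
    @property
    def conv1_side(self) -> int:
        return (self.M - self.KO) // self.SO + 1

    @property
    def MC(self) -> int:
        """Pooled (= merged conv-pool) feature-map side."""
        if (self.M - self.KR) % self.SR != 0:
            raise ValueError(
                f"merged conv-pool geometry does not tile: M={self.M}, "
                f"KR={self.KR}, SR={self.SR}"
            )
        return (self.M - self.KR) // self.SR + 1

    @property
    def MD(self) -> int:
        """Depthwise-separable feature-map side."""
        return self.MC - self.KD + 1

    @property
    def n_blocks(self) -> int:
        """Number of overlapping input blocks in blockwise inference."""
        return self.MD * self.MD

    @property
    def block_side(self) -> int:
        """Input block side: KR + SR*(KD-1)."""
        return self.KR + self.SR * (self.KD - 1)

    @property
    def fc1_in(self) -> int:
        """FC1 input width: flattened DSC map plus the RR code bits."""
        return self.MD * self.MD * self.KP + self.rr_bits

    def validate(self) -> "ModelConfig":
        if min(self.M, self.K, self.KO, self.SO, self.P, self.SP,
               self.KD, self.KP, self.F1, self.C) < 1 or self.rr_bits < 0:
            raise ValueError("all configuration sizes must be positive")
        if self.M < self.KO:
            raise ValueError("image smaller than first-layer kernel")
        _ = self.MC  # raises on non-tiling geometry
        if self.MD < 1:
            raise ValueError("depthwise kernel larger than pooled map")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d).validate()


DEFAULT_CONFIG = ModelConfig()
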