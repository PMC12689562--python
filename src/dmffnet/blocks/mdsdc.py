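"""Multi-Scale Depthwise Separable Dilated Convolution (MDSDC) block.

An ASPP-style encoder stage made cheap with separable convolutions and
recalibrated by dual attention.  Five parallel branches see the input:

1. a 1x1 convolution,
2-4. depthwise 3x3 convolutions at dilations (6, 12, 18), each followed by a
     pointwise 1x1 projection,
5. global average pooling -> 1x1 convolution -> bilinear upsample back to the
   input grid.

Branch outputs concatenate along channels and a 1x1 projection reduces them to
``out_channels``, giving the combined map F.  F is then recalibrated twice —
by an SE-style channel gate (global average pool -> FC bottleneck -> sigmoid)
and by a spatial gate (channel-wise avg & max maps -> 1x1 conv -> sigmoid) —
and the two gated maps are summed with F itself (residual) before a final
square 1x1 projection.

Replacing the dense 3x3 dilated branch of classic ASPP with its depthwise
separable counterpart shrinks the branch weight count from k^2*C_in*C_b to
k^2*C_in + C_in*C_b, roughly a k^2-fold saving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError, ShapeError

__all__ = ["MDSDCConfig", "MDSDCBlock",
           "separable_branch_weight_count", "dense_branch_weight_count"]


def separable_branch_weight_count(c_in: int, c_b: int, k: int = 3) -> int:
    """Conv-weight elements of a depthwise-separable branch: k^2*C_in + C_in*C_b."""
    return k * k * c_in + c_in * c_b


def dense_branch_weight_count(c_in: int, c_b: int, k: int = 3) -> int:
    """Conv-weight elements of the dense k x k branch it replaces."""
    return k * k * c_in * c_b


@dataclass
class MDSDCConfig:
    in_channels: int
    branch_channels: int
    out_channels: int
    dilations: tuple[int, int, int] = (6, 12, 18)
    attention_reduction: int = 16

    def validate(self) -> None:
        if self.branch_channels < 1:
            raise ConfigurationError("branch_channels must be >= 1")
        d = tuple(self.dilations)
        if len(d) != 3 or any(x <= 0 for x in d) or not (d[0] < d[1] < d[2]):
            raise ConfigurationError(
                f"dilations must be three strictly increasing positives, got {d}")
        if self.attention_reduction < 1:
            raise ConfigurationError("attention_reduction must be >= 1")
        if self.out_channels % self.attention_reduction:
            raise ConfigurationError(
                f"attention_reduction {self.attention_reduction} must divide "
                f"out_channels {self.out_channels}")


class _SeparableDilatedBranch(nn.Module):
    """Depthwise 3x3 dilated conv + pointwise projection, BN+ReLU after each."""

    def __init__(self, c_in: int, c_b: int, dilation: int, rng):
        super().__init__()
        self.depthwise = nn.Conv2d(c_in, c_in, 3, dilation=dilation,
                                   groups=c_in, bias=False, rng=rng)
        self.bn_dw = nn.BatchNorm2d(c_in)
        self.pointwise = nn.Conv2d(c_in, c_b, 1, bias=False, rng=rng)
        self.bn_pw = nn.BatchNorm2d(c_b)

    def forward(self, x):
        x = self.bn_dw(self.depthwise(x)).relu()
        return self.bn_pw(self.pointwise(x)).relu()

    def conv_weight_count(self) -> int:
        return self.depthwise.weight.data.size + self.pointwise.weight.data.size


class MDSDCBlock(nn.Module):
    def __init__(self, cfg: MDSDCConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c_in, c_b = cfg.in_channels, cfg.branch_channels

        self.branch1 = nn.Sequential(nn.Conv2d(c_in, c_b, 1, bias=False, rng=rng),
                                     nn.BatchNorm2d(c_b), nn.ReLU())
        self.branch2 = _SeparableDilatedBranch(c_in, c_b, cfg.dilations[0], rng)
        self.branch3 = _SeparableDilatedBranch(c_in, c_b, cfg.dilations[1], rng)
        self.branch4 = _SeparableDilatedBranch(c_in, c_b, cfg.dilations[2], rng)
        # global-context branch: pool -> 1x1 conv -> upsample at forward time
        self.branch5_conv = nn.Sequential(nn.Conv2d(c_in, c_b, 1, bias=False, rng=rng),
                                          nn.BatchNorm2d(c_b), nn.ReLU())

        self.project = nn.Sequential(nn.Conv2d(5 * c_b, cfg.out_channels, 1,
                                               bias=False, rng=rng),
                                     nn.BatchNorm2d(cfg.out_channels), nn.ReLU())

        c = cfg.out_channels
        r = cfg.attention_reduction
        self.fc1 = nn.Linear(c, c // r, rng=rng)
        self.fc2 = nn.Linear(c // r, c, rng=rng)
        self.spatial_conv = nn.Conv2d(2, 1, 1, rng=rng)
        # final square projection, BN only (no activation)
        self.final = nn.Sequential(nn.Conv2d(c, c, 1, bias=False, rng=rng),
                                   nn.BatchNorm2d(c))

    # -- pieces, exposed for inspection and testing ---------------------------
    def branches(self, x: nn.Tensor) -> nn.Tensor:
        """Concatenation of the five parallel branch outputs (width 5*C_b)."""
        if x.shape[1] != self.cfg.in_channels:
            raise ShapeError(f"expected {self.cfg.in_channels} input channels, "
                             f"got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        op5 = nn.bilinear_resize(self.branch5_conv(pooled), (h, w))
        return nn.concat([self.branch1(x), self.branch2(x), self.branch3(x),
                          self.branch4(x), op5], axis=1)

    def channel_attention(self, f: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """SE-style gate: returns (gated map, per-channel weights in (0,1))."""
        b, c = f.shape[0], f.shape[1]
        f_avg = f.mean(axis=(2, 3), keepdims=False)             # (B, C)
        w_c = self.fc2(self.fc1(f_avg).relu()).sigmoid()        # (B, C)
        w_c4 = w_c.reshape(b, c, 1, 1)
        return w_c4 * f, w_c

    def spatial_attention(self, f: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Positional gate from channel-avg and channel-max maps."""
        avg_map = f.mean(axis=1, keepdims=True)
        max_map = f.max(axis=1, keepdims=True)
        w_s = self.spatial_conv(nn.concat([avg_map, max_map], axis=1)).sigmoid()
        return w_s * f, w_s

    def forward(self, x: nn.Tensor, return_intermediates: bool = False):
        f = self.project(self.branches(x))
        f_c, w_c = self.channel_attention(f)
        f_s, w_s = self.spatial_attention(f)
        fused = f_c + f_s + f          # dual attention + residual
        out = self.final(fused)
        if return_intermediates:
            return out, {"combined": f, "channel_weights": w_c,
                         "spatial_weights": w_s, "fused": fused}
        return out

    # -- accounting -----------------------------------------------------------
    def branch_conv_weight_counts(self) -> list[int]:
        """Conv-weight elements per branch (BN and bias excluded)."""
        return [self.branch1.layers[0].weight.data.size,
                self.branch2.conv_weight_count(),
                self.branch3.conv_weight_count(),
                self.branch4.conv_weight_count(),
                self.branch5_conv.layers[0].weight.data.size]
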