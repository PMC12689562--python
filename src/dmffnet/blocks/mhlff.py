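"""Middle--High-Level Feature Fusion (MHLFF).

Fuses the backbone's mid-level tap with the (processed) high-level path:

* mid path:  1x1 conv -> BN,
* high path: 1x1 conv (channel reduction) -> bilinear x2 upsample -> 3x3 conv
  with dilation 2 -> BN,
* output:    ReLU(mid + high), at the mid tap's resolution.

No activation is applied inside either path; the single ReLU after the sum is
the only nonlinearity, so the output is elementwise non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError, ShapeError

__all__ = ["MHLFFConfig", "MHLFFBlock"]


@dataclass
class MHLFFConfig:
    mid_channels: int
    high_channels: int
    fused_channels: int
    dilation: int = 2
    upsample_factor: int = 2

    def validate(self) -> None:
        if self.fused_channels < 1:
            raise ConfigurationError("fused_channels must be >= 1")
        if self.dilation < 1 or self.upsample_factor < 1:
            raise ConfigurationError("dilation and upsample_factor must be >= 1")


class MHLFFBlock(nn.Module):
    def __init__(self, cfg: MHLFFConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.mid_conv = nn.Conv2d(cfg.mid_channels, cfg.fused_channels, 1,
                                  bias=False, rng=rng)
        self.mid_bn = nn.BatchNorm2d(cfg.fused_channels)
        self.high_reduce = nn.Conv2d(cfg.high_channels, cfg.fused_channels, 1,
                                     bias=False, rng=rng)
        self.high_conv = nn.Conv2d(cfg.fused_channels, cfg.fused_channels, 3,
                                   dilation=cfg.dilation, bias=False, rng=rng)
        self.high_bn = nn.BatchNorm2d(cfg.fused_channels)

    def forward(self, f_m: nn.Tensor, f_h: nn.Tensor) -> nn.Tensor:
        hm, wm = f_m.shape[2], f_m.shape[3]
        hh, wh = f_h.shape[2], f_h.shape[3]
        k = self.cfg.upsample_factor
        if (hh * k, wh * k) != (hm, wm):
            raise ShapeError(
                f"high tap {hh}x{wh} upsampled x{k} gives {hh * k}x{wh * k}, "
                f"which does not match the mid tap {hm}x{wm}")
        op1 = self.mid_bn(self.mid_conv(f_m))
        up = nn.bilinear_resize(self.high_reduce(f_h), (hm, wm))
        op2 = self.high_bn(self.high_conv(up))
        return (op1 + op2).relu()
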