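"""Global Group Coordinate Attention (GGCAM) decoder block.

Channels are split into G contiguous groups.  For each group, average and max
pooling collapse the height axis (profiles over width) and the width axis
(profiles over height).  A single shared bottleneck (1x1 conv -> BN -> ReLU ->
1x1 conv), applied to the avg+max sum of each direction, produces two sigmoid
gates; the group output is ``A_h * F_g + A_w * F_g`` with each gate broadcast
along its collapsed axis.  Groups re-concatenate in order, so the output shape
always equals the input shape.

With the shared bottleneck zero-initialized, both gates are exactly 0.5 and
the block is the identity — a useful property for inserting it into a trained
or ablated pipeline without perturbing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError

__all__ = ["GGCAMConfig", "GGCAMBlock", "group_split", "directional_pool"]


@dataclass
class GGCAMConfig:
    channels: int
    groups: int = 4
    reduction: int = 1

    def validate(self) -> None:
        if self.groups < 1 or self.channels % self.groups:
            raise ConfigurationError(
                f"groups ({self.groups}) must divide channels ({self.channels})")
        per_group = self.channels // self.groups
        if self.reduction < 1 or per_group % self.reduction:
            raise ConfigurationError(
                f"reduction ({self.reduction}) must divide channels-per-group "
                f"({per_group})")


def group_split(f: nn.Tensor, groups: int) -> list[nn.Tensor]:
    """Split channels into ``groups`` contiguous slices, in order."""
    c = f.shape[1]
    if groups < 1 or c % groups:
        raise ConfigurationError(f"groups ({groups}) must divide channels ({c})")
    per = c // groups
    return [f.narrow(1, g * per, per) for g in range(groups)]


def directional_pool(f_g: nn.Tensor):
    """Average/max pooled profiles along height and width.

    Returns ``(avg_h, max_h, avg_w, max_w)`` where the ``_h`` maps collapse the
    height axis (shape (B, C, 1, W)) and the ``_w`` maps collapse the width
    axis (shape (B, C, H, 1)).
    """
    avg_h = f_g.mean(axis=2, keepdims=True)
    max_h = f_g.max(axis=2, keepdims=True)
    avg_w = f_g.mean(axis=3, keepdims=True)
    max_w = f_g.max(axis=3, keepdims=True)
    return avg_h, max_h, avg_w, max_w


class GGCAMBlock(nn.Module):
    def __init__(self, cfg: GGCAMConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        per = cfg.channels // cfg.groups
        hidden = per // cfg.reduction
        # one bottleneck shared across groups and both directions
        self.shared = nn.Sequential(
            nn.Conv2d(per, hidden, 1, bias=False, rng=rng),
            nn.BatchNorm2d(hidden),
            nn.ReLU(),
            nn.Conv2d(hidden, per, 1, bias=False, rng=rng),
        )

    def gates(self, avg_h, max_h, avg_w, max_w) -> tuple[nn.Tensor, nn.Tensor]:
        """Directional sigmoid gates from the summed pooled profiles."""
        a_h = self.shared(avg_h + max_h).sigmoid()
        a_w = self.shared(avg_w + max_w).sigmoid()
        return a_h, a_w

    def forward(self, f: nn.Tensor) -> nn.Tensor:
        if f.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"GGCAM built for {self.cfg.channels} channels, got {f.shape[1]}")
        outs = []
        for f_g in group_split(f, self.cfg.groups):
            a_h, a_w = self.gates(*directional_pool(f_g))
            outs.append(a_h * f_g + a_w * f_g)
        return nn.concat(outs, axis=1)
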