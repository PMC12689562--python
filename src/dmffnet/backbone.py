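"""Feature-extraction backbones with two tap points.

The network consumes two feature maps from its encoder backbone: a mid-level
tap at stride 8 and a high-level tap at the output stride (8 or 16).  Two
backbones are provided:

``tiny``
    Four plain conv stages (channels 16/32/64/128, each nominally stride 2);
    at output stride 8 the last stage trades its stride for dilation 2.  It is
    small enough that unit tests and desk-scale training need no pretrained
    weights, and it initializes deterministically from a seed.

``mobilenet-like``
    A MobileNetV2-flavoured inverted-residual encoder (expansion 4) — the
    default for realistic use, still trained from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError

__all__ = ["BackboneTaps", "Backbone", "TinyBackbone", "MobileNetLikeBackbone",
           "build_backbone", "extract_taps"]


@dataclass
class BackboneTaps:
    """Mid- and high-level feature maps from one forward pass."""

    mid: nn.Tensor
    high: nn.Tensor
    strides: tuple[int, int]


def _conv_bn_relu(c_in, c_out, k, rng, *, stride=1, dilation=1, groups=1):
    return nn.Sequential(
        nn.Conv2d(c_in, c_out, k, stride=stride, dilation=dilation,
                  groups=groups, bias=False, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    )


class Backbone(nn.Module):
    """Base class; subclasses set tap metadata and implement forward_taps."""

    mid_channels: int
    high_channels: int
    strides: tuple[int, int]

    def forward_taps(self, x: nn.Tensor) -> BackboneTaps:  # pragma: no cover
        raise NotImplementedError

    def forward(self, x: nn.Tensor) -> BackboneTaps:
        return self.forward_taps(x)


class TinyBackbone(Backbone):
    """4-stage conv encoder; channels 16/32/64/128, strides 2/2/2/2.

    With ``output_stride=8`` the final stage uses dilation 2 at stride 1, so
    both taps share the stride-8 grid.
    """

    def __init__(self, output_stride: int, rng: np.random.Generator):
        super().__init__()
        if output_stride not in (8, 16):
            raise ConfigurationError(f"output_stride must be 8 or 16, got {output_stride}")
        chans = (16, 32, 64, 128)
        self.stage1 = _conv_bn_relu(3, chans[0], 3, rng, stride=2)
        self.stage2 = _conv_bn_relu(chans[0], chans[1], 3, rng, stride=2)
        self.stage3 = _conv_bn_relu(chans[1], chans[2], 3, rng, stride=2)
        if output_stride == 16:
            self.stage4 = _conv_bn_relu(chans[2], chans[3], 3, rng, stride=2)
        else:
            self.stage4 = _conv_bn_relu(chans[2], chans[3], 3, rng, stride=1, dilation=2)
        self.mid_channels = chans[2]
        self.high_channels = chans[3]
        self.strides = (8, output_stride)

    def forward_taps(self, x: nn.Tensor) -> BackboneTaps:
        mid = self.stage3(self.stage2(self.stage1(x)))
        high = self.stage4(mid)
        return BackboneTaps(mid=mid, high=high, strides=self.strides)


class _InvertedResidual(nn.Module):
    def __init__(self, c_in, c_out, rng, *, stride=1, dilation=1, expand=4):
        super().__init__()
        hidden = c_in * expand
        self.use_residual = stride == 1 and c_in == c_out
        self.expand = _conv_bn_relu(c_in, hidden, 1, rng)
        self.depthwise = _conv_bn_relu(hidden, hidden, 3, rng, stride=stride,
                                       dilation=dilation, groups=hidden)
        self.project = nn.Sequential(
            nn.Conv2d(hidden, c_out, 1, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
        )

    def forward(self, x):
        out = self.project(self.depthwise(self.expand(x)))
        return out + x if self.use_residual else out


class MobileNetLikeBackbone(Backbone):
    """Inverted-residual encoder; mid tap is the last stride-8 stage."""

    def __init__(self, output_stride: int, rng: np.random.Generator):
        super().__init__()
        if output_stride not in (8, 16):
            raise ConfigurationError(f"output_stride must be 8 or 16, got {output_stride}")
        self.stem = _conv_bn_relu(3, 16, 3, rng, stride=2)           # stride 2
        self.stage2 = nn.Sequential(
            _InvertedResidual(16, 24, rng, stride=2),                # stride 4
            _InvertedResidual(24, 24, rng),
        )
        self.stage3 = nn.Sequential(
            _InvertedResidual(24, 32, rng, stride=2),                # stride 8
            _InvertedResidual(32, 32, rng),
        )
        if output_stride == 16:
            stride4, dil4 = 2, 1
        else:
            stride4, dil4 = 1, 2
        self.stage4 = nn.Sequential(
            _InvertedResidual(32, 64, rng, stride=stride4),
            _InvertedResidual(64, 64, rng, dilation=dil4),
            _InvertedResidual(64, 96, rng, dilation=dil4),
        )
        self.mid_channels = 32
        self.high_channels = 96
        self.strides = (8, output_stride)

    def forward_taps(self, x: nn.Tensor) -> BackboneTaps:
        mid = self.stage3(self.stage2(self.stem(x)))
        high = self.stage4(mid)
        return BackboneTaps(mid=mid, high=high, strides=self.strides)


_BACKBONES = {"tiny": TinyBackbone, "mobilenet-like": MobileNetLikeBackbone}


def build_backbone(name: str, output_stride: int, *, seed: int = 0) -> Backbone:
    """Construct a backbone with deterministic seed-derived initialization."""
    if name not in _BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {name!r}; choose from {sorted(_BACKBONES)}")
    if output_stride not in (8, 16):
        raise ConfigurationError(f"output_stride must be 8 or 16, got {output_stride}")
    rng = np.random.default_rng(seed)
    return _BACKBONES[name](output_stride, rng)


def extract_taps(backbone: Backbone, images: nn.Tensor | np.ndarray) -> BackboneTaps:
    """Run the backbone and return its two tap feature maps.

    ``images`` is NCHW with 3 channels; both spatial sizes must be divisible
    by the high-tap stride.
    """
    if not isinstance(images, nn.Tensor):
        images = nn.Tensor(images)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ShapeError(f"expected (B, 3, H, W) input, got {images.shape}")
    s_high = backbone.strides[1]
    _, _, h, w = images.shape
    for axis_name, n in (("height", h), ("width", w)):
        if n % s_high:
            raise ShapeError(
                f"input {axis_name} {n} is not divisible by the high-tap stride {s_high}")
    return backbone.forward_taps(images)
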