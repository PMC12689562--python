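"""Full segmentation network: backbone -> MDSDC -> MHLFF -> GGCAM -> head.

The encoder is a two-tap backbone whose high-level features pass through the
MDSDC block; the decoder fuses them with the mid-level tap (MHLFF), reweights
the fused map (GGCAM), and a 1x1 classifier plus bilinear upsampling produces
per-pixel lesion logits at input resolution.  Each of the three blocks can be
switched off independently, which expresses the baseline / +MHLFF / +MDSDC /
+GGCAM ablation ladder:

* MDSDC off  -> replaced by a 1x1 projection to the same width,
* MHLFF off  -> the mid tap is bypassed (decoder runs at the high-tap stride),
* GGCAM off  -> identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import Backbone, build_backbone, extract_taps
from .blocks import (GGCAMBlock, GGCAMConfig, MDSDCBlock, MDSDCConfig,
                     MHLFFBlock, MHLFFConfig)
from .exceptions import ConfigurationError

__all__ = ["NetworkConfig", "DMFFNet", "build_model", "count_parameters",
           "count_macs", "layer_table", "export_attention_heatmap"]


@dataclass
class NetworkConfig:
    backbone_name: str = "mobilenet-like"
    output_stride: int = 16
    num_classes: int = 1
    input_size: int = 512
    use_mdsdc: bool = True
    use_ggcam: bool = True
    use_mhlff: bool = True
    mdsdc_branch_channels: int = 64
    mdsdc_out_channels: int = 128
    mdsdc_dilations: tuple[int, int, int] = (6, 12, 18)
    mdsdc_reduction: int = 16
    ggcam_groups: int = 4
    ggcam_reduction: int = 1
    mhlff_fused_channels: int = 128

    def validate(self) -> list[str]:
        problems = []
        if self.output_stride not in (8, 16):
            problems.append(f"output_stride must be 8 or 16, got {self.output_stride}")
        elif self.input_size % self.output_stride:
            problems.append(f"input_size {self.input_size} not divisible by "
                            f"output_stride {self.output_stride}")
        if self.num_classes < 1:
            problems.append("num_classes must be >= 1")
        return problems

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mdsdc_dilations"] = list(d["mdsdc_dilations"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "mdsdc_dilations" in d:
            d["mdsdc_dilations"] = tuple(d["mdsdc_dilations"])
        return cls(**d)


class DMFFNet(nn.Module):
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        problems = cfg.validate()
        if problems:
            raise ConfigurationError("; ".join(problems))
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.backbone: Backbone = build_backbone(cfg.backbone_name, cfg.output_stride,
                                                 seed=int(rng.integers(2 ** 31)))
        high_ch = self.backbone.high_channels
        mid_ch = self.backbone.mid_channels
        enc_out = cfg.mdsdc_out_channels

        if cfg.use_mdsdc:
            self.encoder = MDSDCBlock(MDSDCConfig(
                in_channels=high_ch, branch_channels=cfg.mdsdc_branch_channels,
                out_channels=enc_out, dilations=cfg.mdsdc_dilations,
                attention_reduction=cfg.mdsdc_reduction), rng)
        else:
            self.encoder = nn.Sequential(nn.Conv2d(high_ch, enc_out, 1, bias=False, rng=rng),
                                         nn.BatchNorm2d(enc_out), nn.ReLU())

        s_mid, s_high = self.backbone.strides
        if cfg.use_mhlff:
            self.mhlff = MHLFFBlock(MHLFFConfig(
                mid_channels=mid_ch, high_channels=enc_out,
                fused_channels=cfg.mhlff_fused_channels,
                upsample_factor=s_high // s_mid), rng)
            dec_ch, self.dec_stride = cfg.mhlff_fused_channels, s_mid
        else:
            self.mhlff = None
            dec_ch, self.dec_stride = enc_out, s_high

        if cfg.use_ggcam:
            self.ggcam = GGCAMBlock(GGCAMConfig(
                channels=dec_ch, groups=cfg.ggcam_groups,
                reduction=cfg.ggcam_reduction), rng)
        else:
            self.ggcam = nn.Identity()

        self.head = nn.Conv2d(dec_ch, cfg.num_classes, 1, bias=True, rng=rng)

    @staticmethod
    def _check_finite(t: nn.Tensor, block: str) -> None:
        if not np.all(np.isfinite(t.data)):
            raise RuntimeError(f"non-finite activations after {block}")

    def forward(self, images, record: dict | None = None) -> nn.Tensor:
        """Return per-pixel logits at input resolution.

        ``record`` (optional dict) receives the ``encoder_final`` and
        ``decoder_final`` feature maps for heatmap export.
        """
        if not isinstance(images, nn.Tensor):
            images = nn.Tensor(images)
        h, w = images.shape[2], images.shape[3]
        taps = extract_taps(self.backbone, images)
        self._check_finite(taps.high, "backbone")
        enc = self.encoder(taps.high)
        self._check_finite(enc, "encoder (MDSDC)")
        if self.mhlff is not None:
            dec_in = self.mhlff(taps.mid, enc)
            self._check_finite(dec_in, "MHLFF")
        else:
            dec_in = enc
        dec = self.ggcam(dec_in)
        self._check_finite(dec, "GGCAM")
        logits = nn.bilinear_resize(self.head(dec), (h, w))
        self._check_finite(logits, "classifier head")
        if record is not None:
            record["encoder_final"] = enc
            record["decoder_final"] = dec
        return logits


def build_model(cfg: NetworkConfig, seed: int = 0) -> DMFFNet:
    return DMFFNet(cfg, seed=seed)


def count_parameters(module: nn.Module) -> int:
    """Exact number of trainable weight elements."""
    return module.num_parameters()


def _module_macs(mod: nn.Module) -> int | None:
    if isinstance(mod, nn.Conv2d):
        return mod.macs()
    if isinstance(mod, nn.Linear):
        return mod.in_features * mod.out_features
    return None


def count_macs(model: DMFFNet, input_size: int | None = None) -> int:
    """Analytic multiply–accumulate count for one image.

    Runs a single forward pass at ``input_size`` (default: the configured
    size) to record per-conv output sizes, then sums k^2*C_in*C_out*H*W/groups
    per conv layer plus in*out per fully connected layer.  FLOPs, under the
    2-ops-per-MAC convention, are twice this number.
    """
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    model.forward(np.zeros((1, 3, size, size)))
    model.train(was_training)
    total = 0
    for _, mod in model.named_modules():
        m = _module_macs(mod)
        if m is not None:
            total += m
    return total


def layer_table(model: DMFFNet, input_size: int | None = None) -> list[dict]:
    """Per-layer accounting rows: name, type, parameter count, MACs."""
    count_macs(model, input_size)  # refresh recorded output sizes
    rows = []
    for name, mod in model.named_modules():
        if isinstance(mod, (nn.Conv2d, nn.Linear, nn.BatchNorm2d)):
            rows.append({
                "name": name,
                "type": type(mod).__name__,
                "params": sum(p.data.size for p in mod._parameters.values()
                              if p is not None),
                "macs": _module_macs(mod) or 0,
            })
    return rows


def export_attention_heatmap(model: DMFFNet, image: np.ndarray,
                             stage: str = "decoder_final") -> np.ndarray:
    """Channel-mean activation heatmap, min–max normalized, at image size.

    ``image`` is (H, W, 3) in [0, 1].  A spatially constant feature map maps
    to an all-zero heatmap (degenerate normalization).  Returns (H, W) floats
    in [0, 1].
    """
    if stage not in ("encoder_final", "decoder_final"):
        raise ConfigurationError(f"unknown heatmap stage {stage!r}")
    h, w = image.shape[:2]
    batch = image.transpose(2, 0, 1)[None]
    record: dict = {}
    was_training = model.training
    model.eval()
    model.forward(batch, record=record)
    model.train(was_training)
    fm = record[stage].data.mean(axis=1, keepdims=True)  # (1, 1, h', w')
    lo, hi = fm.min(), fm.max()
    if hi - lo < 1e-12:
        fm = np.zeros_like(fm)
    else:
        fm = (fm - lo) / (hi - lo)
    heat = nn.bilinear_resize(nn.Tensor(fm), (h, w)).data[0, 0]
    return np.clip(heat, 0.0, 1.0)
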