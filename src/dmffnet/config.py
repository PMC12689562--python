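"""YAML configuration parsing.

Config layout (all keys optional; defaults shown in the dataclasses)::

    seed: 0
    backbone: {name: mobilenet-like, output_stride: 16}
    mdsdc:  {enabled: true, branch_channels: 64, out_channels: 128,
             dilations: [6, 12, 18], reduction: 16}
    ggcam:  {enabled: true, groups: 4, reduction: 1}
    mhlff:  {enabled: true, fused_channels: 128}
    model:  {num_classes: 1, input_size: 512}
    train:  {epochs: 180, batch_size: 8, optimizer: sgd, momentum: 0.9,
             base_lr: 0.007, poly_power: 0.9, augment: true}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import NetworkConfig
from .train import TrainConfig

__all__ = ["load_config", "network_config_from_dict", "train_config_from_dict"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def network_config_from_dict(cfg: dict) -> NetworkConfig:
    backbone = cfg.get("backbone", {})
    mdsdc = cfg.get("mdsdc", {})
    ggcam = cfg.get("ggcam", {})
    mhlff = cfg.get("mhlff", {})
    model = cfg.get("model", {})
    defaults = NetworkConfig()
    return NetworkConfig(
        backbone_name=backbone.get("name", defaults.backbone_name),
        output_stride=backbone.get("output_stride", defaults.output_stride),
        num_classes=model.get("num_classes", defaults.num_classes),
        input_size=model.get("input_size", defaults.input_size),
        use_mdsdc=mdsdc.get("enabled", True),
        use_ggcam=ggcam.get("enabled", True),
        use_mhlff=mhlff.get("enabled", True),
        mdsdc_branch_channels=mdsdc.get("branch_channels", defaults.mdsdc_branch_channels),
        mdsdc_out_channels=mdsdc.get("out_channels", defaults.mdsdc_out_channels),
        mdsdc_dilations=tuple(mdsdc.get("dilations", defaults.mdsdc_dilations)),
        mdsdc_reduction=mdsdc.get("reduction", defaults.mdsdc_reduction),
        ggcam_groups=ggcam.get("groups", defaults.ggcam_groups),
        ggcam_reduction=ggcam.get("reduction", defaults.ggcam_reduction),
        mhlff_fused_channels=mhlff.get("fused_channels", defaults.mhlff_fused_channels),
    )


def train_config_from_dict(cfg: dict) -> TrainConfig:
    train = cfg.get("train", {})
    model = cfg.get("model", {})
    defaults = TrainConfig()
    return TrainConfig(
        epochs=train.get("epochs", defaults.epochs),
        batch_size=train.get("batch_size", defaults.batch_size),
        optimizer=train.get("optimizer", defaults.optimizer),
        momentum=train.get("momentum", defaults.momentum),
        base_lr=train.get("base_lr", defaults.base_lr),
        poly_power=train.get("poly_power", defaults.poly_power),
        input_size=model.get("input_size", defaults.input_size),
        seed=cfg.get("seed", defaults.seed),
        augment=train.get("augment", defaults.augment),
        checkpoint_dir=train.get("checkpoint_dir", defaults.checkpoint_dir),
        log_path=train.get("log_path", defaults.log_path),
    )
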