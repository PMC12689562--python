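"""Training, evaluation, prediction, and checkpointing.

Training optimizes per-pixel binary cross-entropy over sigmoid logits with
SGD+momentum (default, lr 7e-3 decayed by the poly schedule) or Adam.  All
randomness — initialization, data order, augmentation — derives from a single
seed, so repeated runs on the same machine are bit-reproducible.

Checkpoints are ``.npz`` archives holding the flat model state dict plus the
JSON-encoded network configuration, so a checkpoint alone rebuilds the model.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .data import ImageMaskPair, augment, preprocess
from .metrics import MetricReport, bce_loss, poly_lr
from .model import DMFFNet, NetworkConfig, build_model, export_attention_heatmap

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 180
    batch_size: int = 8
    optimizer: str = "sgd"          # "sgd" or "adam"
    momentum: float = 0.9
    base_lr: float = 7e-3
    poly_power: float = 0.9
    input_size: int = 512
    seed: int = 0
    augment: bool = True
    checkpoint_dir: str | Path = "checkpoints"
    log_path: str | Path | None = None

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"optimizer must be 'sgd' or 'adam', got {self.optimizer!r}")


@dataclass
class TrainResult:
    epoch_losses: list[float]
    epoch_lrs: list[float]
    val_mious: list[float]
    best_val_miou: float
    best_checkpoint: Path
    last_checkpoint: Path


def _to_batch(pairs: list[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image.transpose(2, 0, 1) for p in pairs])
    masks = np.stack([p.mask for p in pairs])[:, None].astype(np.float64)
    return images, masks


def save_checkpoint(model: DMFFNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __network_config__=json.dumps(model.cfg.to_dict()), **state)
    return path


def load_checkpoint(path: str | Path) -> DMFFNet:
    with np.load(Path(path), allow_pickle=False) as archive:
        cfg = NetworkConfig.from_dict(json.loads(str(archive["__network_config__"])))
        state = {k: archive[k] for k in archive.files if k != "__network_config__"}
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model


def train(net_cfg: NetworkConfig, train_cfg: TrainConfig,
          train_pairs: list[ImageMaskPair],
          val_pairs: list[ImageMaskPair] | None = None) -> TrainResult:
    """Run the full training loop; returns losses and checkpoint paths."""
    train_cfg.validate()
    problems = net_cfg.validate()
    if problems:
        raise ValueError("; ".join(problems))
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(net_cfg, seed=int(rng.integers(2 ** 31)))

    train_pairs = [preprocess(p, net_cfg.input_size) for p in train_pairs]
    val_pairs = [preprocess(p, net_cfg.input_size) for p in (val_pairs or train_pairs)]

    if train_cfg.optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=train_cfg.base_lr,
                     momentum=train_cfg.momentum)
    else:
        opt = nn.Adam(model.parameters(), lr=train_cfg.base_lr)

    steps_per_epoch = max(1, int(np.ceil(len(train_pairs) / train_cfg.batch_size)))
    max_iter = train_cfg.epochs * steps_per_epoch
    ckpt_dir = Path(train_cfg.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    log_rows = []

    iteration = 0
    best_miou = -1.0
    epoch_losses, epoch_lrs, val_mious = [], [], []
    best_path = ckpt_dir / "best.npz"
    last_path = ckpt_dir / "last.npz"

    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(len(train_pairs))
        losses = []
        epoch_first_lr = None
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch = [train_pairs[i] for i in idx]
            if train_cfg.augment:
                batch = [augment(p, np.random.default_rng(rng.integers(2 ** 31)))
                         for p in batch]
            images, masks = _to_batch(batch)
            lr = poly_lr(iteration, max_iter, train_cfg.base_lr, train_cfg.poly_power)
            if epoch_first_lr is None:
                epoch_first_lr = lr
            opt.lr = lr
            logits = model.forward(images)
            loss = bce_loss(logits.sigmoid(), masks)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch ids "
                    f"{[batch[i].id for i in range(len(batch))]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            iteration += 1
        mean_loss = float(np.mean(losses))
        epoch_losses.append(mean_loss)
        epoch_lrs.append(epoch_first_lr)

        report = evaluate(model, val_pairs, input_size=net_cfg.input_size)
        miou = report.aggregate["miou"]
        val_mious.append(miou)
        if miou > best_miou:
            best_miou = miou
            save_checkpoint(model, best_path)
        save_checkpoint(model, last_path)
        log.info("epoch %d/%d: loss=%.5f lr=%.5g val_miou=%.4f",
                 epoch + 1, train_cfg.epochs, mean_loss, epoch_first_lr, miou)
        log_rows.append({"epoch": epoch + 1, "mean_loss": mean_loss,
                         "lr": epoch_first_lr, "val_miou": miou})

    if train_cfg.log_path:
        with open(train_cfg.log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "mean_loss", "lr",
                                                    "val_miou"])
            writer.writeheader()
            writer.writerows(log_rows)

    return TrainResult(epoch_losses=epoch_losses, epoch_lrs=epoch_lrs,
                       val_mious=val_mious, best_val_miou=best_miou,
                       best_checkpoint=best_path, last_checkpoint=last_path)


def evaluate(model: DMFFNet | str | Path, pairs: list[ImageMaskPair],
             threshold: float = 0.5, input_size: int | None = None,
             batch_size: int = 8) -> MetricReport:
    """Per-image and pooled metrics at the given probability threshold."""
    if not isinstance(model, DMFFNet):
        model = load_checkpoint(model)
    if not pairs:
        raise ValueError("empty dataset")
    size = input_size or model.cfg.input_size
    pairs = [preprocess(p, size) for p in pairs]
    was_training = model.training
    model.eval()
    items = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        images, _ = _to_batch(chunk)
        probs = model.forward(images).sigmoid().data[:, 0]
        for pair, prob in zip(chunk, probs):
            pred = (prob >= threshold).astype(np.uint8)
            items.append((pair.id, pred, pair.mask))
    model.train(was_training)
    return MetricReport.from_pairs(items)


def predict(model: DMFFNet | str | Path, image_paths: list[str | Path],
            out_dir: str | Path, threshold: float = 0.5,
            heatmap_stage: str | None = None) -> list[Path]:
    """Write 0/255 mask PNGs (and optional heatmaps) at original resolution."""
    if not isinstance(model, DMFFNet):
        model = load_checkpoint(model)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    size = model.cfg.input_size
    model.eval()
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            with Image.open(path) as im:
                image = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except OSError as exc:
            log.warning("skipping unreadable image %s (%s)", path, exc)
            continue
        h, w = image.shape[:2]
        pair = preprocess(ImageMaskPair(image, np.zeros(image.shape[:2], np.uint8),
                                        path.stem), size)
        prob = model.forward(pair.image.transpose(2, 0, 1)[None]).sigmoid().data[0, 0]
        mask = (prob >= threshold).astype(np.uint8)
        # nearest-neighbour upsample back to the original resolution
        rows = (np.arange(h) * size // h).clip(0, size - 1)
        cols = (np.arange(w) * size // w).clip(0, size - 1)
        full = mask[np.ix_(rows, cols)] * 255
        out_path = out_dir / f"{path.stem}_mask.png"
        Image.fromarray(full.astype(np.uint8)).save(out_path)
        written.append(out_path)
        if heatmap_stage:
            heat = export_attention_heatmap(model, image, heatmap_stage)
            heat_path = out_dir / f"{path.stem}_heat.png"
            Image.fromarray((heat * 255).astype(np.uint8)).save(heat_path)
            written.append(heat_path)
    if not written:
        raise RuntimeError("no input image could be read")
    return written
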