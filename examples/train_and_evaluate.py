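"""Train the tiny-backbone network on synthetic data and report metrics.

A desk-scale run: 8 synthetic 64x64 images, 60 full-batch iterations with
Adam.  Loss should fall steeply and the training-set MIoU should climb well
above the 0.5 chance level, demonstrating the full pipeline end to end.
"""

from pathlib import Path

from dmffnet import (NetworkConfig, SynthParams, TrainConfig, evaluate,
                     generate_synthetic, load_checkpoint, train)

pairs = generate_synthetic(SynthParams(n=8, size=64, seed=42,
                                       hair_count_range=(0, 2)))
net_cfg = NetworkConfig(backbone_name="tiny", input_size=64)
train_cfg = TrainConfig(epochs=60, batch_size=8, optimizer="adam", base_lr=1e-3,
                        input_size=64, seed=7, augment=False,
                        checkpoint_dir=Path("scratch/example_ckpt"))

result = train(net_cfg, train_cfg, pairs, pairs)
print(f"loss: {result.epoch_losses[0]:.4f} (epoch 1) -> "
      f"{result.epoch_losses[-1]:.4f} (epoch {len(result.epoch_losses)})")
print(f"best training-set MIoU: {result.best_val_miou:.4f}")

report = evaluate(load_checkpoint(result.best_checkpoint), pairs, input_size=64)
agg = report.aggregate
print("aggregate metrics:",
      " ".join(f"{k}={agg[k]:.4f}" for k in report.METRIC_KEYS))
print("MIoU averages lesion and background IoU; values near 1 mean the "
      "predicted masks almost coincide with the ground truth.")
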