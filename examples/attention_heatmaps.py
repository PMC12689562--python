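"""Export encoder/decoder attention heatmaps for a synthetic image.

The heatmap is the channel-mean activation of the chosen stage, min-max
normalized to [0, 1] and upsampled to image resolution — the standard way to
see where the network concentrates: the encoder tends to respond around
lesion boundaries, the decoder over the lesion body.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from dmffnet import (NetworkConfig, SynthParams, build_model,
                     export_attention_heatmap, generate_synthetic)

pair = generate_synthetic(SynthParams(n=1, size=64, seed=5))[0]
model = build_model(NetworkConfig(backbone_name="tiny", input_size=64), seed=0)

out = Path("scratch/heatmaps")
out.mkdir(parents=True, exist_ok=True)
for stage in ("encoder_final", "decoder_final"):
    heat = export_attention_heatmap(model, pair.image, stage)
    Image.fromarray((heat * 255).astype(np.uint8)).save(out / f"{stage}.png")
    print(f"{stage}: heatmap {heat.shape}, range [{heat.min():.3f}, "
          f"{heat.max():.3f}], mean {heat.mean():.3f} -> {out / (stage + '.png')}")
print("Values span [0, 1] by construction; a constant feature map would "
      "export as all zeros.")
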