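"""Dataset reading, preprocessing, and paired augmentation.

Disk layout follows the ISIC challenge convention::

    <root>/<split>/images/*.{jpg,jpeg,png}
    <root>/<split>/masks/*.png         # matching stems; 0/255 lesion masks

Masks binarize at pixel value >= 128 (lesion = 1).  Images load as float RGB
in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as sk_resize

__all__ = ["ImageMaskPair", "load_dataset", "preprocess", "augment",
           "save_pair", "MASK_THRESHOLD"]

log = logging.getLogger(__name__)

MASK_THRESHOLD = 128
_IMAGE_EXTS = (".jpg", ".jpeg", ".png")


@dataclass
class ImageMaskPair:
    image: np.ndarray   # (H, W, 3) float in [0, 1]
    mask: np.ndarray    # (H, W) uint8 in {0, 1}
    id: str

    def validate(self) -> "ImageMaskPair":
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"{self.id}: image {self.image.shape[:2]} and mask "
                             f"{self.mask.shape} sizes differ")
        values = np.unique(self.mask)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"{self.id}: mask is not binary (values {values})")
        return self


def _read_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def _read_mask(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr >= MASK_THRESHOLD).astype(np.uint8)


def load_dataset(root: str | Path, split: str) -> list[ImageMaskPair]:
    """Read matched image/mask pairs, sorted by id; orphans are skipped."""
    base = Path(root) / split
    img_dir, mask_dir = base / "images", base / "masks"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images directory at {img_dir}")
    pairs: list[ImageMaskPair] = []
    stems = sorted(p.stem for p in img_dir.iterdir()
                   if p.suffix.lower() in _IMAGE_EXTS)
    for stem in stems:
        img_path = next(p for p in img_dir.iterdir()
                        if p.stem == stem and p.suffix.lower() in _IMAGE_EXTS)
        mask_path = mask_dir / f"{stem}.png"
        if not mask_path.exists():
            log.warning("image %s has no mask; skipped", img_path.name)
            continue
        pairs.append(ImageMaskPair(_read_image(img_path), _read_mask(mask_path),
                                   stem).validate())
    if not pairs:
        raise FileNotFoundError(f"split {split!r} under {root} contains no "
                                f"matched image/mask pairs")
    log.info("loaded %d pairs from %s/%s", len(pairs), root, split)
    return pairs


def save_pair(pair: ImageMaskPair, root: str | Path, split: str) -> None:
    """Write a pair as PNGs in the standard layout."""
    base = Path(root) / split
    (base / "images").mkdir(parents=True, exist_ok=True)
    (base / "masks").mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.round(pair.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8).save(base / "images" / f"{pair.id}.png")
    Image.fromarray((pair.mask * 255).astype(np.uint8)).save(
        base / "masks" / f"{pair.id}.png")


def preprocess(pair: ImageMaskPair, target_size: int = 512) -> ImageMaskPair:
    """Resize to target: bilinear for the image, nearest for the mask."""
    if pair.image.shape[:2] == (target_size, target_size):
        return pair
    image = sk_resize(pair.image, (target_size, target_size), order=1,
                      anti_aliasing=False, preserve_range=True)
    mask = sk_resize(pair.mask, (target_size, target_size), order=0,
                     anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return ImageMaskPair(np.clip(image, 0.0, 1.0), mask, pair.id).validate()


def augment(pair: ImageMaskPair, seed: int | np.random.Generator,
            crop_scale: tuple[float, float] = (0.8, 1.0),
            flip_prob: float = 0.5) -> ImageMaskPair:
    """Seeded joint augmentation: random H/V flips and random crop.

    The crop takes an independently scaled fraction of each side (then
    resizes back), applied identically to image and mask; flips each fire
    with probability ``flip_prob``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    image, mask = pair.image, pair.mask
    if rng.random() < flip_prob:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < flip_prob:
        image, mask = image[::-1], mask[::-1]
    h, w = mask.shape
    sy, sx = rng.uniform(crop_scale[0], crop_scale[1], size=2)
    ch, cw = max(1, int(round(h * sy))), max(1, int(round(w * sx)))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    image = image[top:top + ch, left:left + cw]
    mask = mask[top:top + ch, left:left + cw]
    if (ch, cw) != (h, w):
        image = np.clip(sk_resize(image, (h, w), order=1, anti_aliasing=False,
                                  preserve_range=True), 0.0, 1.0)
        mask = sk_resize(mask, (h, w), order=0, anti_aliasing=False,
                         preserve_range=True).astype(np.uint8)
    return ImageMaskPair(np.ascontiguousarray(image),
                         np.ascontiguousarray(mask), pair.id).validate()
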