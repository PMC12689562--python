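"""Synthetic dermoscopy generator.

Emulates the qualitative challenges of dermoscopic lesion images — irregular
lesion shapes, blurred boundaries, low contrast, and hair occlusion — with a
fully deterministic procedure so the entire pipeline can be exercised without
any external dataset:

* background: skin-toned base color with a gentle illumination gradient and
  mild pixel noise;
* lesion: an ellipse-like region whose radius is perturbed by a random sum of
  low-order sinusoidal harmonics of the polar angle (controllable
  irregularity); filled with a darker brown, alpha-blended through a Gaussian
  blur of the support so the boundary is soft;
* hairs: thin dark polylines drawn over the image (drawn last, so a zero hair
  count leaves the render untouched);
* contrast: the image is scaled about mid-gray into a sampled contrast factor.

The binary mask is the pre-blur lesion support.  Each sample is a pure
function of ``(seed, index)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

from .data import ImageMaskPair, save_pair

__all__ = ["SynthParams", "generate_synthetic", "write_dataset"]


@dataclass
class SynthParams:
    n: int = 16
    size: int = 128
    lesion_area_range: tuple[float, float] = (0.05, 0.40)
    boundary_blur_sigma: float = 2.0
    hair_count_range: tuple[int, int] = (0, 4)
    contrast_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"lesion_area_range must lie inside (0, 1), got {self.lesion_area_range}")
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.hair_count_range[0] > self.hair_count_range[1] or self.hair_count_range[0] < 0:
            raise ValueError(f"bad hair_count_range {self.hair_count_range}")


_SKIN = np.array([0.85, 0.66, 0.55])
_LESION = np.array([0.45, 0.29, 0.24])
_HAIR = np.array([0.13, 0.10, 0.08])


def _lesion_support(rng: np.random.Generator, size: int,
                    area_range: tuple[float, float]) -> np.ndarray:
    """Irregular lesion mask via radial sinusoidal perturbation; rejection
    sampled until the area fraction lands in ``area_range``."""
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(100):
        target = rng.uniform(*area_range)
        base_r = size * np.sqrt(target / np.pi)
        cy, cx = rng.uniform(0.35, 0.65, size=2) * size
        aspect = rng.uniform(0.7, 1.4)
        theta0 = rng.uniform(0, 2 * np.pi)
        n_harm = rng.integers(2, 5)
        amps = rng.uniform(0.03, 0.12, size=n_harm)
        freqs = rng.integers(2, 7, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)

        dy, dx = yy - cy, xx - cx
        # rotate into the ellipse frame
        c, s = np.cos(theta0), np.sin(theta0)
        u = c * dx + s * dy
        v = (-s * dx + c * dy) * aspect
        rr = np.hypot(u, v)
        ang = np.arctan2(v, u)
        pert = np.ones_like(ang)
        for a, f, p in zip(amps, freqs, phases):
            pert += a * np.sin(f * ang + p)
        mask = (rr <= base_r * pert).astype(np.uint8)
        frac = mask.mean()
        if area_range[0] <= frac <= area_range[1]:
            return mask
    raise RuntimeError(f"could not draw a lesion with area fraction in "
                       f"{area_range} after 100 attempts")


def _draw_hairs(image: np.ndarray, rng: np.random.Generator, n_hairs: int) -> None:
    size = image.shape[0]
    for _ in range(n_hairs):
        # a 3-segment polyline crossing part of the frame
        pts = rng.integers(0, size, size=(4, 2))
        shade = _HAIR * rng.uniform(0.8, 1.2)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
            image[rr, cc] = 0.25 * image[rr, cc] + 0.75 * shade


def _render(params: SynthParams, index: int) -> ImageMaskPair:
    rng = np.random.default_rng([params.seed, index])
    size = params.size
    mask = _lesion_support(rng, size, params.lesion_area_range)

    # skin background with illumination gradient and texture noise
    gy, gx = rng.uniform(-0.08, 0.08, size=2)
    ramp = (np.linspace(-0.5, 0.5, size)[:, None] * gy
            + np.linspace(-0.5, 0.5, size)[None, :] * gx)
    tint = rng.uniform(-0.04, 0.04, size=3)
    image = (_SKIN + tint)[None, None, :] + ramp[:, :, None]
    image = image + rng.normal(0.0, 0.015, size=(size, size, 3))

    lesion_color = _LESION + rng.uniform(-0.05, 0.05, size=3)
    soft = gaussian_filter(mask.astype(np.float64), params.boundary_blur_sigma)
    image = image * (1.0 - soft[:, :, None]) + lesion_color[None, None, :] * soft[:, :, None]

    contrast = rng.uniform(*params.contrast_range)
    image = 0.5 + (image - 0.5) * contrast

    n_hairs = int(rng.integers(params.hair_count_range[0],
                               params.hair_count_range[1] + 1))
    if n_hairs > 0:
        _draw_hairs(image, rng, n_hairs)

    image = np.clip(image, 0.0, 1.0)
    pair = ImageMaskPair(image, mask, f"synth_{params.seed:05d}_{index:04d}")
    pair.n_hairs = n_hairs  # type: ignore[attr-defined]  # manifest metadata
    return pair.validate()


def generate_synthetic(params: SynthParams) -> list[ImageMaskPair]:
    """Generate ``params.n`` deterministic image/mask pairs."""
    params.validate()
    return [_render(params, i) for i in range(params.n)]


def write_dataset(params: SynthParams, root: str | Path, split: str = "train") -> list[ImageMaskPair]:
    """Generate and write pairs in the on-disk layout, plus a manifest.csv."""
    pairs = generate_synthetic(params)
    root = Path(root)
    for pair in pairs:
        save_pair(pair, root, split)
    with open(root / split / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "area_fraction", "n_hairs", "seed"])
        for pair in pairs:
            writer.writerow([pair.id, f"{pair.mask.mean():.6f}",
                             getattr(pair, "n_hairs", 0), params.seed])
    return pairs
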