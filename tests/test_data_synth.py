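"""Dataset I/O, preprocessing, augmentation, and the synthetic generator."""

import dataclasses

import numpy as np
import pytest

from dmffnet import (ImageMaskPair, SynthParams, augment, generate_synthetic,
                     load_dataset, preprocess, write_dataset)
from dmffnet.data import save_pair


def test_load_dataset_sorted_threshold_and_orphan_skip(tmp_path, caplog):
    from PIL import Image
    base = tmp_path / "train"
    (base / "images").mkdir(parents=True)
    (base / "masks").mkdir()
    rng = np.random.default_rng(0)
    for stem in ("b_img", "a_img", "c_orphan"):
        Image.fromarray(rng.integers(0, 255, size=(10, 10, 3), dtype=np.uint8)
                        ).save(base / "images" / f"{stem}.png")
    # mask values straddle the 128 binarization threshold
    mask = np.array([[200, 12], [128, 127]], dtype=np.uint8).repeat(5, 0).repeat(5, 1)
    for stem in ("a_img", "b_img"):
        Image.fromarray(mask).save(base / "masks" / f"{stem}.png")
    pairs = load_dataset(tmp_path, "train")
    assert [p.id for p in pairs] == ["a_img", "b_img"]   # orphan skipped, sorted
    quad = pairs[0].mask[::5, ::5]
    assert quad.tolist() == [[1, 0], [1, 0]]             # >=128 -> 1

    with pytest.raises(FileNotFoundError):
        load_dataset(tmp_path, "missing_split")


def test_png_roundtrip_preserves_masks_and_images(tmp_path):
    params = SynthParams(n=3, size=48, seed=5)
    pairs = generate_synthetic(params)
    for pair in pairs:
        save_pair(pair, tmp_path, "train")
    loaded = load_dataset(tmp_path, "train")
    assert len(loaded) == 3
    for orig, back in zip(pairs, loaded):
        assert np.array_equal(orig.mask, back.mask)
        assert np.abs(orig.image - back.image).max() <= 1.0 / 255.0 + 1e-12


def test_preprocess_resizes_and_keeps_mask_binary():
    rng = np.random.default_rng(1)
    pair = ImageMaskPair(rng.uniform(size=(45, 60, 3)),
                         rng.integers(0, 2, size=(45, 60)).astype(np.uint8), "p")
    out = preprocess(pair, 32)
    assert out.image.shape == (32, 32, 3)
    assert out.mask.shape == (32, 32)
    assert set(np.unique(out.mask)) <= {0, 1}
    # already at target size: mask is returned exactly
    same = preprocess(out, 32)
    assert np.array_equal(same.mask, out.mask)


def test_augment_is_deterministic_and_preserves_invariants(synth_pairs_32):
    pair = synth_pairs_32[0]
    a = augment(pair, seed=99)
    b = augment(pair, seed=99)
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)
    assert set(np.unique(a.mask)) <= {0, 1}
    assert a.image.min() >= 0.0 and a.image.max() <= 1.0
    assert a.image.shape == pair.image.shape


def test_flips_are_area_preserving_involutions(synth_pairs_32):
    pair = synth_pairs_32[1]
    flipped = ImageMaskPair(pair.image[:, ::-1], pair.mask[:, ::-1], pair.id)
    assert flipped.mask.sum() == pair.mask.sum()
    assert np.array_equal(flipped.mask[:, ::-1], pair.mask)


def test_generator_is_deterministic_per_seed_and_index():
    params = SynthParams(n=4, size=64, seed=7)
    a = generate_synthetic(params)
    b = generate_synthetic(params)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.image, pb.image)
        assert np.array_equal(pa.mask, pb.mask)
    # different seed changes the render
    c = generate_synthetic(dataclasses.replace(params, seed=8))
    assert not np.array_equal(a[0].image, c[0].image)


def test_lesion_area_fractions_respect_range():
    params = SynthParams(n=8, size=64, seed=3, lesion_area_range=(0.10, 0.30))
    for pair in generate_synthetic(params):
        assert 0.10 <= pair.mask.mean() <= 0.30


def test_unsatisfiable_area_range_raises():
    params = SynthParams(n=1, size=64, seed=0, lesion_area_range=(0.898, 0.899))
    with pytest.raises(RuntimeError, match="100 attempts"):
        generate_synthetic(params)


def test_hair_toggle_changes_only_the_overlay():
    base = SynthParams(n=2, size=64, seed=21, hair_count_range=(0, 0))
    hairy = dataclasses.replace(base, hair_count_range=(3, 3))
    a = generate_synthetic(base)
    b = generate_synthetic(hairy)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.mask, pb.mask)      # lesion geometry unchanged
        assert not np.array_equal(pa.image, pb.image)  # polylines drawn
    assert all(getattr(p, "n_hairs") == 0 for p in a)


def test_write_dataset_layout_and_manifest(tmp_path):
    params = SynthParams(n=2, size=48, seed=1)
    write_dataset(params, tmp_path, "val")
    assert sorted(p.name for p in (tmp_path / "val" / "images").iterdir()) == \
        sorted(p.name for p in (tmp_path / "val" / "masks").iterdir())
    manifest = (tmp_path / "val" / "manifest.csv").read_text().strip().splitlines()
    assert manifest[0] == "id,area_fraction,n_hairs,seed"
    assert len(manifest) == 3
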