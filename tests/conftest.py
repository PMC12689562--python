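import numpy as np
import pytest

from dmffnet import ImageMaskPair, NetworkConfig, SynthParams, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_cfg():
    """Smallest full network: tiny backbone at 32x32 with narrow blocks."""
    return NetworkConfig(backbone_name="tiny", input_size=32,
                         mdsdc_branch_channels=16, mdsdc_out_channels=32,
                         mdsdc_reduction=4, mhlff_fused_channels=32,
                         ggcam_groups=4)


@pytest.fixture(scope="session")
def synth_pairs_32():
    params = SynthParams(n=4, size=32, seed=11, boundary_blur_sigma=1.0,
                         hair_count_range=(0, 1))
    return generate_synthetic(params)


def checkerboard_pair(size: int = 16) -> ImageMaskPair:
    mask = np.indices((size, size)).sum(axis=0) % 2
    image = np.stack([mask * 0.5 + 0.25] * 3, axis=-1)
    return ImageMaskPair(image.astype(np.float64), mask.astype(np.uint8), "checker")
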