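"""MDSDC block: branch geometry, attention closed forms, parameter economy."""

import numpy as np
import pytest

from dmffnet import MDSDCBlock, MDSDCConfig, nn
from dmffnet.blocks import dense_branch_weight_count, separable_branch_weight_count
from dmffnet.exceptions import ConfigurationError, ShapeError

from oracles import naive_dilated_depthwise_conv


def small_block(rng, c_in=8, c_b=4, c_out=8, reduction=4):
    return MDSDCBlock(MDSDCConfig(in_channels=c_in, branch_channels=c_b,
                                  out_channels=c_out, attention_reduction=reduction),
                      rng)


def zero_attention(block):
    for lin in (block.fc1, block.fc2):
        lin.weight.data[...] = 0.0
        lin.bias.data[...] = 0.0
    block.spatial_conv.weight.data[...] = 0.0
    block.spatial_conv.bias.data[...] = 0.0


def identity_final(block):
    c = block.cfg.out_channels
    block.final.layers[0].weight.data[...] = np.eye(c)[:, :, None, None]
    block.final.layers[1].eps = 0.0  # BN with stats (0, 1) is then exactly identity


def test_config_validation():
    with pytest.raises(ConfigurationError, match="dilations"):
        MDSDCConfig(8, 4, 8, dilations=(6, 6, 18)).validate()
    with pytest.raises(ConfigurationError, match="attention_reduction"):
        MDSDCConfig(8, 4, 9, attention_reduction=4).validate()


def test_branch_concat_width_and_spatial_size(rng):
    block = small_block(rng)
    out = block.branches(nn.Tensor(rng.normal(size=(2, 8, 12, 10))))
    assert out.shape == (2, 5 * 4, 12, 10)
    with pytest.raises(ShapeError):
        block.branches(nn.Tensor(rng.normal(size=(2, 7, 12, 10))))


def test_global_branch_of_constant_input_is_spatially_constant(rng):
    block = small_block(rng).eval()
    x = nn.Tensor(np.broadcast_to(np.arange(8.0)[:, None, None],
                                  (8, 9, 9)).copy()[None])
    out = block.branches(x).data
    op5 = out[:, 16:20]  # fifth branch occupies the last C_b channels
    # pooling a per-channel constant and upsampling keeps it constant
    assert np.ptp(op5.reshape(4, -1), axis=1).max() < 1e-9


@pytest.mark.parametrize("dilation", [6, 12, 18])
def test_depthwise_dilated_conv_matches_naive_loop(rng, dilation):
    x = rng.normal(size=(1, 3, 16, 16))
    w = rng.normal(size=(3, 1, 3, 3))
    fast = nn.conv2d(nn.Tensor(x), nn.Tensor(w), stride=1, padding=dilation,
                     dilation=dilation, groups=3).data
    assert np.abs(fast - naive_dilated_depthwise_conv(x, w, dilation)).max() < 1e-5


def test_impulse_response_lands_on_dilated_taps():
    # all-ones depthwise kernel at dilation 6 answers only at offsets {-6,0,6}^2
    x = np.zeros((1, 1, 13, 13))
    x[0, 0, 6, 6] = 1.0
    w = np.ones((1, 1, 3, 3))
    out = nn.conv2d(nn.Tensor(x), nn.Tensor(w), padding=6, dilation=6, groups=1).data
    nz = np.argwhere(out[0, 0] != 0)
    expected = {(6 + du, 6 + dv) for du in (-6, 0, 6) for dv in (-6, 0, 6)}
    assert {tuple(p) for p in nz} == expected


def test_channel_attention_closed_form(rng):
    block = small_block(rng)
    # per-channel constant map: F_avg recovers the constants
    consts = np.arange(1.0, 9.0)
    f = nn.Tensor(np.broadcast_to(consts[:, None, None], (8, 5, 5)).copy()[None])
    zero_attention(block)
    weighted, w_c = block.channel_attention(f)
    assert np.allclose(w_c.data, 0.5)           # sigma(0) at zero parameters
    assert np.allclose(weighted.data, 0.5 * f.data)
    # bounds hold for arbitrary parameters and inputs
    block2 = small_block(np.random.default_rng(5))
    _, w = block2.channel_attention(nn.Tensor(rng.normal(size=(2, 8, 6, 6))))
    assert np.all((w.data > 0) & (w.data < 1))


def test_spatial_attention_closed_form_and_channel_symmetry(rng):
    block = small_block(rng)
    zero_attention(block)
    f = nn.Tensor(rng.normal(size=(2, 8, 6, 6)))
    weighted, w_s = block.spatial_attention(f)
    assert np.allclose(w_s.data, 0.5)
    assert np.allclose(weighted.data, 0.5 * f.data)
    # the gate sees only channel-avg and channel-max, so any channel
    # permutation of F leaves it unchanged
    block2 = small_block(np.random.default_rng(6))
    perm = rng.permutation(8)
    _, w_a = block2.spatial_attention(f)
    _, w_b = block2.spatial_attention(nn.Tensor(f.data[:, perm]))
    assert np.allclose(w_a.data, w_b.data)


def test_forward_doubles_combined_map_at_zero_attention(rng):
    block = small_block(rng)
    zero_attention(block)
    identity_final(block)
    block.eval()
    x = nn.Tensor(rng.normal(size=(2, 8, 7, 7)))
    out, inter = block.forward(x, return_intermediates=True)
    assert np.abs(out.data - 2.0 * inter["combined"].data).max() < 1e-5


def test_zero_input_gives_zero_output(rng):
    block = small_block(rng).eval()
    out = block(nn.Tensor(np.zeros((1, 8, 6, 6))))
    # all convs are bias-free and BN is affine around zero at init
    assert np.abs(out.data).max() < 1e-12


def test_output_shape_contract(rng):
    block = MDSDCBlock(MDSDCConfig(in_channels=20, branch_channels=8,
                                   out_channels=16, attention_reduction=4), rng)
    out = block(nn.Tensor(rng.normal(size=(2, 20, 9, 11))))
    assert out.shape == (2, 16, 9, 11)
    assert np.all(np.isfinite(out.data))


def test_separable_branch_weight_counts_match_formula(rng):
    # the worked numbers: C_in=320, C_b=256
    assert separable_branch_weight_count(320, 256) == 84_800
    assert dense_branch_weight_count(320, 256) == 737_280
    block = small_block(rng, c_in=320, c_b=256, c_out=320, reduction=16)
    counts = block.branch_conv_weight_counts()
    for dilated_branch in counts[1:4]:
        assert dilated_branch == separable_branch_weight_count(320, 256)
        assert dilated_branch * 8 < dense_branch_weight_count(320, 256)
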