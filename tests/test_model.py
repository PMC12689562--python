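"""Assembled network: shapes, determinism, ablation ladder, accounting,
heatmaps."""

import numpy as np
import pytest

import dmffnet as d
from dmffnet import nn
from dmffnet.exceptions import ConfigurationError


def test_logits_shape_and_finiteness(tiny_net_cfg, rng):
    model = d.build_model(tiny_net_cfg, seed=0)
    x = rng.normal(size=(2, 3, 32, 32))
    logits = model.forward(x)
    assert logits.shape == (2, 1, 32, 32)
    assert np.all(np.isfinite(logits.data))
    probs = logits.sigmoid().data
    assert np.all((probs > 0) & (probs < 1))


def test_same_seed_same_initial_forward(tiny_net_cfg, rng):
    x = rng.normal(size=(1, 3, 32, 32))
    a = d.build_model(tiny_net_cfg, seed=9).forward(x).data
    b = d.build_model(tiny_net_cfg, seed=9).forward(x).data
    assert np.array_equal(a, b)


def test_batch_independence(tiny_net_cfg, rng):
    model = d.build_model(tiny_net_cfg, seed=2).eval()
    img = rng.normal(size=(1, 3, 32, 32))
    two = model.forward(np.concatenate([img, img])).data
    assert np.allclose(two[0], two[1])


def test_invalid_config_lists_violations():
    cfg = d.NetworkConfig(backbone_name="tiny", input_size=30, num_classes=0)
    with pytest.raises(ConfigurationError, match="divisible.*num_classes|input_size"):
        d.build_model(cfg)


def test_all_flags_off_is_backbone_plus_projection(tiny_net_cfg, rng):
    import dataclasses
    cfg = dataclasses.replace(tiny_net_cfg, use_mdsdc=False, use_ggcam=False,
                              use_mhlff=False)
    model = d.build_model(cfg, seed=0)
    assert isinstance(model.encoder, nn.Sequential)
    assert model.mhlff is None
    assert isinstance(model.ggcam, nn.Identity)
    out = model.forward(rng.normal(size=(1, 3, 32, 32)))
    assert out.shape == (1, 1, 32, 32)


def test_zero_init_ggcam_matches_ggcam_off(tiny_net_cfg, rng):
    import dataclasses
    on = d.build_model(tiny_net_cfg, seed=4)
    off = d.build_model(dataclasses.replace(tiny_net_cfg, use_ggcam=False), seed=4)
    # identical weights everywhere except the (zeroed) attention bottleneck
    state = {k: v for k, v in on.state_dict().items() if not k.startswith("ggcam")}
    off_state = off.state_dict()
    for k, v in state.items():
        off_state[k][...] = v
    off.load_state_dict(off_state)
    on.ggcam.shared.zero_parameters()
    x = rng.normal(size=(1, 3, 32, 32))
    on.eval(), off.eval()
    assert np.allclose(on.forward(x).data, off.forward(x).data, atol=1e-9)


def test_ablation_ladder_parameter_deltas(tiny_net_cfg):
    import dataclasses
    full = d.build_model(tiny_net_cfg, seed=0)
    # GGCAM off: delta is exactly the attention block's own count
    no_ggcam = d.build_model(dataclasses.replace(tiny_net_cfg, use_ggcam=False), seed=0)
    assert (d.count_parameters(full) - d.count_parameters(no_ggcam)
            == full.ggcam.num_parameters())
    # MHLFF off: delta is exactly the fusion block's own count
    no_mhlff = d.build_model(dataclasses.replace(tiny_net_cfg, use_mhlff=False), seed=0)
    assert (d.count_parameters(full) - d.count_parameters(no_mhlff)
            == full.mhlff.num_parameters())
    # MDSDC off: replaced by a 1x1 projection, so delta is block minus projection
    no_mdsdc = d.build_model(dataclasses.replace(tiny_net_cfg, use_mdsdc=False), seed=0)
    assert (d.count_parameters(full) - d.count_parameters(no_mdsdc)
            == full.encoder.num_parameters() - no_mdsdc.encoder.num_parameters())
    high_ch = full.backbone.high_channels
    c_out = tiny_net_cfg.mdsdc_out_channels
    assert no_mdsdc.encoder.num_parameters() == high_ch * c_out + 2 * c_out


def test_parameter_count_formulas(rng):
    conv = nn.Conv2d(320, 256, 1, bias=False, rng=rng)
    assert conv.weight.data.size == 81_920
    dense = nn.Conv2d(320, 256, 3, bias=False, rng=rng)
    assert dense.weight.data.size == 737_280
    dw = nn.Conv2d(320, 320, 3, groups=320, bias=False, rng=rng)
    pw = nn.Conv2d(320, 256, 1, bias=False, rng=rng)
    assert dw.weight.data.size + pw.weight.data.size == 84_800


def test_analytic_macs_for_single_conv(rng):
    conv = nn.Conv2d(320, 256, 3, bias=False, rng=rng)
    conv(nn.Tensor(np.zeros((1, 320, 32, 32))))
    assert conv.macs() == 737_280 * 1024


def test_count_macs_and_layer_table(tiny_net_cfg):
    model = d.build_model(tiny_net_cfg, seed=0)
    macs = d.count_macs(model, 32)
    rows = d.layer_table(model, 32)
    assert macs > 0
    assert sum(r["macs"] for r in rows) == macs
    assert sum(r["params"] for r in rows) == d.count_parameters(model)


def test_heatmap_contract_and_degenerate_case(tiny_net_cfg, rng):
    model = d.build_model(tiny_net_cfg, seed=1)
    image = rng.uniform(size=(32, 32, 3))
    for stage in ("encoder_final", "decoder_final"):
        heat = d.export_attention_heatmap(model, image, stage)
        assert heat.shape == (32, 32)
        assert heat.min() >= 0.0 and heat.max() <= 1.0
    # constant feature map -> all-zero heatmap by convention
    for p in model.parameters():
        p.data[...] = 0.0
    heat = d.export_attention_heatmap(model, image, "decoder_final")
    assert np.all(heat == 0.0)


def test_forward_speed_at_desk_scale(tiny_net_cfg):
    import dataclasses
    import time
    cfg = dataclasses.replace(tiny_net_cfg, input_size=64)
    model = d.build_model(cfg, seed=0).eval()
    x = np.zeros((1, 3, 64, 64))
    model.forward(x)  # warm up caches
    t0 = time.perf_counter()
    model.forward(x)
    assert time.perf_counter() - t0 < 1.0
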