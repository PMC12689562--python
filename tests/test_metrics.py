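"""Metric formulas against brute-force counting; BCE and poly-LR checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmffnet import (ConfusionCounts, MetricReport, bce_loss, confusion_counts,
                     metrics_from_counts, poly_lr)
from dmffnet.nn import Tensor

from oracles import brute_force_metrics, scalar_bce


def test_confusion_counts_worked_example():
    gt = np.array([[1, 1], [0, 0]])
    pred = np.array([[1, 0], [0, 0]])
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 2)
    # swapping prediction and truth swaps fp <-> fn
    c2 = confusion_counts(gt, pred)
    assert (c2.fp, c2.fn) == (c.fn, c.fp)


def test_confusion_counts_validation():
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros((2, 2)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="binary"):
        confusion_counts(np.array([[2, 0]]), np.array([[1, 0]]))


def test_metrics_worked_example():
    m = metrics_from_counts(ConfusionCounts(tp=1, tn=2, fp=0, fn=1))
    assert m["acc"] == 0.75
    assert m["precision"] == 1.0
    assert np.isclose(m["f1"], 2 / 3)
    assert np.isclose(m["miou"], 7 / 12)       # (1/2 + 2/3) / 2
    assert np.isclose(m["mrecall"], 0.75)      # (1/2 + 1) / 2


def test_perfect_prediction_scores_one_everywhere():
    m = metrics_from_counts(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
    assert all(np.isclose(v, 1.0) for v in m.values())


def test_absent_class_scores_one_only_when_absent_from_both():
    both_empty = metrics_from_counts(ConfusionCounts(tp=0, tn=9, fp=0, fn=0))
    assert both_empty["miou"] == 1.0 and both_empty["precision"] == 1.0
    false_alarm = metrics_from_counts(ConfusionCounts(tp=0, tn=8, fp=1, fn=0))
    assert false_alarm["precision"] == 0.0 and false_alarm["miou"] < 1.0


def test_metrics_match_bruteforce_on_random_masks(rng):
    for _ in range(100):
        pred = rng.integers(0, 2, size=(16, 16))
        gt = rng.integers(0, 2, size=(16, 16))
        fast = metrics_from_counts(confusion_counts(pred, gt))
        slow = brute_force_metrics(pred, gt)
        assert fast == slow


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_metrics_invariant_under_joint_pixel_permutation(seed):
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, 2, size=64)
    gt = rng.integers(0, 2, size=64)
    perm = rng.permutation(64)
    a = metrics_from_counts(confusion_counts(pred, gt))
    b = metrics_from_counts(confusion_counts(pred[perm], gt[perm]))
    assert a == b


def test_report_pools_counts_and_serializes(tmp_path, rng):
    items = [(f"im{i}", rng.integers(0, 2, size=(8, 8)).astype(np.uint8),
              rng.integers(0, 2, size=(8, 8)).astype(np.uint8)) for i in range(3)]
    report = MetricReport.from_pairs(items)
    assert len(report.per_image) == 3
    pooled = ConfusionCounts(0, 0, 0, 0)
    for _, p, g in items:
        pooled = pooled + confusion_counts(p, g)
    assert report.aggregate == metrics_from_counts(pooled)
    report.to_json(tmp_path / "r.json")
    assert MetricReport.from_json(tmp_path / "r.json").aggregate == report.aggregate
    report.to_csv(tmp_path / "r.csv")
    assert (tmp_path / "r.csv").read_text().count("aggregate") == 1


def test_bce_analytic_values():
    assert np.isclose(bce_loss(np.array([0.5]), np.array([1.0])), np.log(2))
    assert bce_loss(np.array([1.0]), np.array([1.0])) <= 1e-6
    batch = bce_loss(np.array([0.8, 0.3]), np.array([1.0, 0.0]))
    assert np.isclose(batch, (-np.log(0.8) - np.log(0.7)) / 2, atol=1e-6)


def test_bce_matches_scalar_loop_and_tensor_path(rng):
    p = rng.uniform(0.01, 0.99, size=(4, 17))
    y = rng.integers(0, 2, size=(4, 17)).astype(float)
    fast = bce_loss(p, y)
    assert np.isclose(fast, scalar_bce(p, y), rtol=1e-9)
    tensor_val = bce_loss(Tensor(p), y)
    assert np.isclose(float(tensor_val.data), fast, rtol=1e-12)


def test_bce_rejects_nonbinary_labels():
    with pytest.raises(ValueError, match="binary"):
        bce_loss(np.array([0.5]), np.array([0.3]))


def test_poly_lr_endpoints_midpoint_and_clamp():
    assert poly_lr(0, 100) == 7e-3
    assert poly_lr(100, 100) == 0.0
    assert np.isclose(poly_lr(50, 100, base_lr=1.0, power=1.0), 0.5)
    lrs = [poly_lr(i, 50, base_lr=0.1, power=0.9) for i in range(51)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    with pytest.warns(UserWarning):
        assert poly_lr(101, 100) == 0.0
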