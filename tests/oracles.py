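"""Independent brute-force references used to validate the fast paths.

Everything here is written with plain Python loops / direct formula
evaluation and never calls into ``dmffnet.nn``.
"""

from __future__ import annotations

import numpy as np


def naive_dilated_depthwise_conv(x: np.ndarray, weight: np.ndarray,
                                 dilation: int) -> np.ndarray:
    """Direct-loop depthwise 3x3 dilated cross-correlation, zero padding
    sized to preserve the spatial dimensions.

    ``x`` is (B, C, H, W); ``weight`` is (C, 1, 3, 3).
    """
    b, c, h, w = x.shape
    pad = dilation
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros_like(x)
    for bi in range(b):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for u in range(3):
                        for v in range(3):
                            acc += weight[ci, 0, u, v] * xp[bi, ci,
                                                            i + u * dilation,
                                                            j + v * dilation]
                    out[bi, ci, i, j] = acc
    return out


def brute_force_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """Per-pixel counting and direct formula evaluation for both classes."""
    tp = tn = fp = fn = 0
    for p, g in zip(pred.ravel().tolist(), gt.ravel().tolist()):
        if p == 1 and g == 1:
            tp += 1
        elif p == 0 and g == 0:
            tn += 1
        elif p == 1 and g == 0:
            fp += 1
        else:
            fn += 1

    def ratio(num, den, absent):
        return (1.0 if absent else 0.0) if den == 0 else num / den

    fg_absent = tp + fp + fn == 0
    bg_absent = tn + fn + fp == 0
    acc = (tp + tn) / (tp + tn + fp + fn)
    iou_fg = ratio(tp, tp + fp + fn, fg_absent)
    iou_bg = ratio(tn, tn + fn + fp, bg_absent)
    rec_fg = ratio(tp, tp + fn, fg_absent)
    rec_bg = ratio(tn, tn + fp, bg_absent)
    prec = ratio(tp, tp + fp, fg_absent)
    f1 = 0.0 if prec + rec_fg == 0 else 2 * prec * rec_fg / (prec + rec_fg)
    return {"miou": 0.5 * (iou_fg + iou_bg), "acc": acc, "f1": f1,
            "mrecall": 0.5 * (rec_fg + rec_bg), "precision": prec}


def _np_sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def naive_ggcam_forward(f: np.ndarray, groups: int, w1: np.ndarray,
                        gamma: np.ndarray, beta: np.ndarray,
                        mean: np.ndarray, var: np.ndarray, eps: float,
                        w2: np.ndarray) -> np.ndarray:
    """Loop reference for the grouped coordinate-attention block (eval-mode
    batch norm with the given running statistics).

    ``w1`` (hidden, per), ``w2`` (per, hidden) are the 1x1 conv weights of the
    shared bottleneck.
    """
    b, c, h, w = f.shape
    per = c // groups
    out = np.zeros_like(f)

    def shared(vec):  # vec: (per,) channel vector at one position
        z = w1 @ vec
        z = (z - mean) / np.sqrt(var + eps) * gamma + beta
        z = np.maximum(z, 0.0)
        return w2 @ z

    for bi in range(b):
        for g in range(groups):
            fg = f[bi, g * per:(g + 1) * per]          # (per, h, w)
            avg_h = fg.mean(axis=1)                     # (per, w)
            max_h = fg.max(axis=1)
            avg_w = fg.mean(axis=2)                     # (per, h)
            max_w = fg.max(axis=2)
            a_h = np.zeros((per, w))
            for j in range(w):
                a_h[:, j] = _np_sigmoid(shared(avg_h[:, j] + max_h[:, j]))
            a_w = np.zeros((per, h))
            for i in range(h):
                a_w[:, i] = _np_sigmoid(shared(avg_w[:, i] + max_w[:, i]))
            for i in range(h):
                for j in range(w):
                    out[bi, g * per:(g + 1) * per, i, j] = (
                        a_h[:, j] * fg[:, i, j] + a_w[:, i] * fg[:, i, j])
    return out


def scalar_bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Scalar-loop binary cross-entropy."""
    total = 0.0
    n = 0
    for pi, yi in zip(p.ravel().tolist(), y.ravel().tolist()):
        pi = min(max(pi, eps), 1.0 - eps)
        total += yi * np.log(pi) + (1.0 - yi) * np.log(1.0 - pi)
        n += 1
    return -total / n
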