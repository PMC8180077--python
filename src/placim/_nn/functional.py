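"""Low-level neural-network primitives on NumPy arrays.

Everything is stride-1, odd-kernel, same-padding 2D cross-correlation in
NCHW layout, float32. Each forward returns ``(output, cache)`` and the
matching backward consumes ``(grad_output, cache)``; gradients are exact
(checked against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padding stride-1 cross-correlation.

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k) with k odd; bias: (Cout,).
    Returns y: (N, Cout, H, W) and a cache for the backward pass.
    """
    k = weight.shape[-1]
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # (N, Cin, H, W, k, k) view over the padded image
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    y = np.einsum("ncijuv,ocuv->noij", cols, weight, optimize=True)
    y += bias[:, None, None]
    return y.astype(DTYPE, copy=False), (cols, weight)


def conv2d_backward(dy: np.ndarray, cache):
    """Gradients of conv2d_forward w.r.t. input, weight and bias."""
    cols, weight = cache
    db = dy.sum(axis=(0, 2, 3))
    dw = np.einsum("noij,ncijuv->ocuv", dy, cols, optimize=True)
    # dx = same-padding correlation of dy with the flipped, transposed kernel
    w_flip = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    dx, _ = conv2d_forward(dy, np.ascontiguousarray(w_flip), np.zeros(weight.shape[1], dtype=DTYPE))
    return dx, dw.astype(DTYPE, copy=False), db.astype(DTYPE, copy=False)


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    # mask of the maximum per 2x2 window, ties broken toward the first
    # occurrence so the backward routing is single-valued
    eq = (xr == y[:, :, :, None, :, None]).transpose(0, 1, 2, 4, 3, 5)
    flat = eq.reshape(n, c, h // 2, w // 2, 4)
    first = np.zeros_like(flat)
    np.put_along_axis(first, flat.argmax(axis=-1)[..., None], True, axis=-1)
    mask = first.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return y, mask


def maxpool2_backward(dy: np.ndarray, mask: np.ndarray):
    n, c, hh, _, ww, _ = mask.shape
    dx = mask * dy[:, :, :, None, :, None]
    return dx.reshape(n, c, hh * 2, ww * 2)


def upsample2_forward(x: np.ndarray):
    """Nearest-neighbour x2 upsampling."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_xent_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy between softmax(logits) and integer labels.

    Returns (loss, dlogits) with dlogits already divided by the batch size.
    """
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff * diff))
    return loss, (2.0 * diff / diff.size).astype(DTYPE)


def dice_bce_loss(logits: np.ndarray, target: np.ndarray):
    """0.5 * (binary cross-entropy + Dice loss) on sigmoid(logits).

    Robust to foreground/background imbalance; returns (loss, dlogits).
    """
    z = logits.astype(np.float64)
    t = target.astype(np.float64)
    p = sigmoid(z)
    n = z.size
    # BCE with logits: softplus(z) - t*z, numerically stable
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dz_bce = (p - t) / n
    eps = 1.0
    num = 2.0 * np.sum(p * t) + eps
    den = np.sum(p) + np.sum(t) + eps
    dice = 1.0 - num / den
    # d(1 - num/den)/dp_i = -(2 t_i * den - num) / den^2
    dp = -(2.0 * t * den - num) / (den * den)
    dz_dice = dp * p * (1.0 - p)
    loss = 0.5 * (bce + dice)
    dz = 0.5 * (dz_bce + dz_dice)
    return loss, dz.astype(DTYPE)
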