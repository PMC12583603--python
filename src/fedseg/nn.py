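"""Minimal numpy layer primitives with explicit forward/backward passes.

All functions operate on float32 arrays shaped ``(N, C, H, W)``. Each
forward returns ``(output, cache)``; the matching backward consumes the
upstream gradient and the cache. Convolutions are computed as nine (or
four) strided matmuls — one per kernel tap — which keeps memory low and
hits BLAS.
"""

from __future__ import annotations

import numpy as np

LRELU_SLOPE = 0.01
NORM_EPS = 1e-5


# ---------------------------------------------------------------- conv2d


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: tuple[int, int]
) -> tuple[np.ndarray, tuple]:
    """2D convolution, padding = kernel//2 per axis (``same`` at stride 1)."""
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    assert cin == cin_w, (cin, cin_w)
    sh, sw = stride
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    y = np.zeros((n, cout, ho, wo), dtype=np.result_type(x, w))
    y2 = y.reshape(n, cout, -1)
    for a in range(kh):
        for c in range(kw):
            xs = xp[:, :, a : a + sh * ho : sh, c : c + sw * wo : sw]
            y2 += np.matmul(w[:, :, a, c], xs.reshape(n, cin, -1))
    y += b[None, :, None, None]
    cache = (xp, w, stride, x.shape, (ho, wo))
    return y, cache


def conv2d_backward(dy: np.ndarray, cache: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xp, w, (sh, sw), x_shape, (ho, wo) = cache
    n, cin = xp.shape[0], xp.shape[1]
    cout, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    dy2 = dy.reshape(n, cout, -1)
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for a in range(kh):
        for c in range(kw):
            xs = xp[:, :, a : a + sh * ho : sh, c : c + sw * wo : sw]
            xs2 = xs.reshape(n, cin, -1)
            dw[:, :, a, c] = np.matmul(dy2, xs2.transpose(0, 2, 1)).sum(axis=0)
            dxs = np.matmul(w[:, :, a, c].T, dy2).reshape(n, cin, ho, wo)
            dxp[:, :, a : a + sh * ho : sh, c : c + sw * wo : sw] += dxs
    db = dy.sum(axis=(0, 2, 3))
    h, wd = x_shape[2], x_shape[3]
    dx = dxp[:, :, ph : ph + h, pw : pw + wd]
    return dx, dw, db


# ------------------------------------------------------ transposed conv


def convtranspose2d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: tuple[int, int]
) -> tuple[np.ndarray, tuple]:
    """Transposed convolution with kernel == stride (1 or 2 per axis).

    Weight layout ``(C_in, C_out, kh, kw)``; each input pixel paints a
    ``kh x kw`` output block, so there is no overlap.
    """
    n, cin, h, wd = x.shape
    cin_w, cout, kh, kw = w.shape
    assert cin == cin_w
    sh, sw = stride
    assert (kh, kw) == (sh, sw), "kernel must equal stride"
    y = np.empty((n, cout, h * sh, wd * sw), dtype=np.result_type(x, w))
    x2 = x.reshape(n, cin, -1)
    for a in range(kh):
        for c in range(kw):
            block = np.matmul(w[:, :, a, c].T, x2).reshape(n, cout, h, wd)
            y[:, :, a::sh, c::sw] = block
    y += b[None, :, None, None]
    return y, (x, w, stride)


def convtranspose2d_backward(
    dy: np.ndarray, cache: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, w, (sh, sw) = cache
    n, cin, h, wd = x.shape
    _, cout, kh, kw = w.shape
    x2 = x.reshape(n, cin, -1)
    dw = np.zeros_like(w)
    dx2 = np.zeros((n, cin, h * wd), dtype=np.result_type(x, w))
    for a in range(kh):
        for c in range(kw):
            dyb = dy[:, :, a::sh, c::sw].reshape(n, cout, -1)
            dw[:, :, a, c] = np.matmul(x2, dyb.transpose(0, 2, 1)).sum(axis=0)
            dx2 += np.matmul(w[:, :, a, c], dyb)
    db = dy.sum(axis=(0, 2, 3))
    return dx2.reshape(x.shape), dw, db


# -------------------------------------------------------- instance norm


def instnorm_forward(
    x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = NORM_EPS
) -> tuple[np.ndarray, tuple]:
    """Instance normalization with affine parameters (statistics are
    recomputed per sample/channel each forward; nothing is tracked)."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    y = g[None, :, None, None] * xhat + b[None, :, None, None]
    return y.astype(x.dtype, copy=False), (xhat, inv, g)


def instnorm_backward(dy: np.ndarray, cache: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=(0, 2, 3))
    db = dy.sum(axis=(0, 2, 3))
    dxhat = dy * g[None, :, None, None]
    m1 = dxhat.mean(axis=(2, 3), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


# ------------------------------------------------------------ leaky ReLU


def lrelu_forward(x: np.ndarray, slope: float = LRELU_SLOPE) -> tuple[np.ndarray, tuple]:
    pos = x > 0
    y = np.where(pos, x, slope * x)
    return y, (pos, slope)


def lrelu_backward(dy: np.ndarray, cache: tuple) -> np.ndarray:
    pos, slope = cache
    return np.where(pos, dy, slope * dy)


# ----------------------------------------------------------------- loss


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def dice_ce_loss_and_grad(
    logits: np.ndarray, target: np.ndarray, *, dice_eps: float = 1e-5
) -> tuple[float, np.ndarray]:
    """Equally weighted soft-Dice + cross-entropy loss and its gradient.

    ``logits``: (N, C, H, W); ``target``: (N, H, W) integer labels.
    The Dice term is computed per foreground class over the whole batch
    (background excluded, as is conventional for overlap losses); the
    cross-entropy term covers all classes.
    """
    n, c = logits.shape[:2]
    p = softmax(logits)
    onehot = np.zeros_like(p)
    flat_t = target.reshape(n, -1)
    onehot.reshape(n, c, -1)[
        np.arange(n)[:, None], flat_t, np.arange(flat_t.shape[1])[None, :]
    ] = 1.0
    npix = float(target.size)

    # cross entropy
    logp = np.log(np.clip(p, 1e-12, None))
    ce = -float((onehot * logp).sum()) / npix
    dlogits = (p - onehot) / npix

    # soft dice over foreground classes, pooled over the batch
    dice_terms = []
    dp = np.zeros_like(p)
    fg_classes = range(1, c)
    for cls in fg_classes:
        pc = p[:, cls]
        gc = onehot[:, cls]
        num = 2.0 * float((pc * gc).sum()) + dice_eps
        den = float(pc.sum() + gc.sum()) + dice_eps
        dice_terms.append(num / den)
        # d(1 - num/den)/dpc = -(2*gc*den - num) / den^2
        dp[:, cls] += -(2.0 * gc * den - num) / (den * den)
    n_fg = max(1, len(list(fg_classes)))
    dice_loss = 1.0 - float(np.mean(dice_terms)) if dice_terms else 0.0
    dp /= n_fg
    # chain through softmax: dz = p * (dp - sum_c dp_c p_c)
    dlogits += p * (dp - (dp * p).sum(axis=1, keepdims=True))

    loss = ce + dice_loss
    return loss, dlogits
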