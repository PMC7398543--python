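"""Low-level neural-network operations on NHWC arrays, with exact gradients.

A compact NumPy engine for the fixed layer set the segmentation network
needs: stride-1 same-padding convolutions (im2col + BLAS matmul), 2x2/2
max-pooling, x2 nearest-neighbor upsampling, ReLU, per-pixel softmax and
categorical cross-entropy.  Every backward pass is the exact analytic
gradient of its forward (verified by numeric differentiation in the test
suite), so plain SGD behaves identically to any other correctly implemented
framework up to floating-point order of evaluation.

Conventions: activations are ``(N, H, W, C)``; convolution weights are
``(kh, kw, c_in, c_out)`` with a per-output-channel bias.  "Same" padding
for an odd kernel is symmetric; for an even kernel the window anchors
top-left (pad 0 before, k-1 after), keeping output size equal to input size
on even grids.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_padding(kh: int, kw: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Per-side zero padding preserving spatial size at stride 1."""
    pt = (kh - 1) // 2
    pl = (kw - 1) // 2
    return (pt, kh - 1 - pt), (pl, kw - 1 - pl)


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N*Ho*Wo, kh*kw*C) patch matrix (Ho=Hp-kh+1)."""
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N, Ho, Wo, C, kh, kw)
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (N, Ho, Wo, kh, kw, C)
    n, ho, wo = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n * ho * wo, kh * kw * xp.shape[3])


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
    pad: tuple[tuple[int, int], tuple[int, int]],
) -> np.ndarray:
    """Stride-1 2D convolution (cross-correlation) with explicit padding."""
    kh, kw, c_in, c_out = w.shape
    xp = np.pad(x, ((0, 0), pad[0], pad[1], (0, 0)))
    n = x.shape[0]
    ho = xp.shape[1] - kh + 1
    wo = xp.shape[2] - kw + 1
    cols = _im2col(xp, kh, kw)
    out = cols @ w.reshape(kh * kw * c_in, c_out)
    if b is not None:
        out += b
    return out.reshape(n, ho, wo, c_out)


def conv2d_backward(
    dout: np.ndarray, x: np.ndarray, w: np.ndarray,
    pad: tuple[tuple[int, int], tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of :func:`conv2d_forward`."""
    kh, kw, c_in, c_out = w.shape
    (pt, pb), (pl, pr) = pad
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    cols = _im2col(xp, kh, kw)
    dout_flat = dout.reshape(-1, c_out)
    dw = (cols.T @ dout_flat).reshape(kh, kw, c_in, c_out)
    db = dout_flat.sum(axis=0)
    # dx is the full correlation of dout with the spatially flipped,
    # channel-transposed kernel; realized by reusing the forward path.
    w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, c_out, c_in)
    dx = conv2d_forward(
        dout, np.ascontiguousarray(w_flip), None,
        ((kh - 1 - pt, kh - 1 - pb), (kw - 1 - pl, kw - 1 - pr)),
    )
    return dx, dw, db


def maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling with stride 2; returns (pooled, argmax indices).

    Spatial dims must be even (guaranteed here: patch sizes are powers-of-two
    multiples of the pooling factor).  Ties take the first window position.
    """
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dout: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Route gradients back to the argmax positions."""
    n, ho, wo, c = dout.shape
    dxr = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(n, ho * 2, wo * 2, c)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    """x2 nearest-neighbor upsampling along both spatial axes."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    """Adjoint of nearest-neighbor upsampling: sum each 2x2 block."""
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the trailing channel axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def categorical_crossentropy(probs: np.ndarray, targets: np.ndarray,
                             eps: float = 1e-12) -> float:
    """Mean cross-entropy over batch and pixels against one-hot targets."""
    return float(-(targets * np.log(probs + eps)).sum() / np.prod(probs.shape[:-1]))


def init_weights(
    shape: tuple[int, int, int, int], scheme: str, rng: np.random.Generator,
    dtype=np.float32,
) -> np.ndarray:
    """He-normal (ReLU default) or Glorot-uniform convolution weight init."""
    kh, kw, c_in, c_out = shape
    fan_in = kh * kw * c_in
    fan_out = kh * kw * c_out
    if scheme == "he_normal":
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    elif scheme == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=shape)
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return w.astype(dtype)
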