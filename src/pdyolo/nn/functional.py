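"""Fused network primitives: convolution, normalisation, pooling, resampling.

Each primitive computes its forward pass in NumPy and registers a
hand-written backward on the autodiff graph.  When a profiling trace is
active (see :func:`profile_trace`) every primitive also records its
multiply-accumulate count so the budget accountant can report FLOPs with
layer-wise closed forms (conv: ``k^2 * Cin * Cout * Hout * Wout / groups``
MACs, linear analogously; each MAC is counted as two FLOPs by the
reporting layer).
"""

from __future__ import annotations

import contextlib

import numpy as np

from .tensor import Tensor, as_tensor

# ---------------------------------------------------------------------------
# profiling trace
# ---------------------------------------------------------------------------

_TRACE: list | None = None


@contextlib.contextmanager
def profile_trace():
    """Collect ``(op_name, macs)`` records for every primitive executed."""
    global _TRACE
    prev, _TRACE = _TRACE, []
    try:
        yield _TRACE
    finally:
        _TRACE = prev


def _record(op: str, macs: float):
    if _TRACE is not None:
        _TRACE.append((op, float(macs)))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xpad: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            hout: int, wout: int) -> np.ndarray:
    b, c = xpad.shape[:2]
    cols = np.empty((b, c, kh, kw, hout, wout), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xpad[:, :, i:i + sh * hout:sh, j:j + sw * wout:sw]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding=0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout; ``padding`` int or (ph, pw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    b, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight expects "
            f"{cin_g}x{groups} (groups)")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    hout = (h + 2 * ph - kh) // stride + 1
    wout = (w + 2 * pw - kw) // stride + 1
    if hout < 1 or wout < 1:
        raise ValueError(f"conv2d output would be empty for input {h}x{w}, "
                         f"kernel {kh}x{kw}, stride {stride}, padding {padding}")
    if ph or pw:
        xpad = np.pad(x.data, ((0, 0), (0, 0), (ph,) * 2, (pw,) * 2))
    else:
        xpad = x.data
    cols = _im2col(xpad, kh, kw, stride, stride, hout, wout)
    # [B, g, (cin/g)*kh*kw, L]
    L = hout * wout
    cols_g = cols.reshape(b, groups, cin_g * kh * kw, L)
    w_g = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.matmul(w_g[None], cols_g)            # [B, g, cout/g, L]
    out = out.reshape(b, cout, hout, wout)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    _record("conv2d", kh * kw * cin_g * cout * L * b)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        g4 = g.reshape(b, groups, cout // groups, L)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.matmul(g4, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w_g.transpose(0, 2, 1)[None], g4)
            dcols = dcols.reshape(b, cin, kh, kw, hout, wout)
            dxpad = np.zeros_like(xpad)
            for i in range(kh):
                for j in range(kw):
                    dxpad[:, :, i:i + stride * hout:stride,
                          j:j + stride * wout:stride] += dcols[:, :, i, j]
            if ph or pw:
                dxpad = dxpad[:, :, ph:ph + h, pw:pw + w]
            x._accumulate(dxpad)

    return Tensor._make(out.astype(np.float32), parents, bw)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """``x @ weight.T + bias`` with MAC recording; x: [..., in]."""
    out = x @ weight.transpose(1, 0)
    _record("linear", x.data.size // x.data.shape[-1]
            * weight.data.shape[0] * weight.data.shape[1])
    if bias is not None:
        out = out + bias
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = b * h * w
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, c, 1, 1) * inv.reshape(1, c, 1, 1)
            if training:
                n = b * h * w
                gsum = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                gxhat = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                dx = gi * (g - gsum / n - xhat * gxhat / n)
            else:
                dx = gi * g
            x._accumulate(dx.astype(np.float32))

    return Tensor._make(out.astype(np.float32), (x, gamma, beta), bw)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """GroupNorm over an NC... tensor (spatial axes optional)."""
    x = as_tensor(x)
    shp = x.data.shape
    b, c = shp[0], shp[1]
    if c % groups:
        raise ValueError(
            f"group_norm: {c} channels not divisible by {groups} groups; "
            f"use a group count dividing the channel count")
    xg = x.data.reshape(b, groups, -1)
    mean = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv).reshape(shp)
    bshape = (1, c) + (1,) * (len(shp) - 2)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def bw(g):
        axes = (0,) + tuple(range(2, len(shp)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            n = xg.shape[2]
            gx = (g * gamma.data.reshape(bshape)).reshape(b, groups, -1)
            xh = xhat.reshape(b, groups, -1)
            gsum = gx.sum(axis=2, keepdims=True)
            gdot = (gx * xh).sum(axis=2, keepdims=True)
            dx = inv * (gx - gsum / n - xh * gdot / n)
            x._accumulate(dx.reshape(shp).astype(np.float32))

    return Tensor._make(out.astype(np.float32), (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    hout = (h + 2 * padding - kernel) // stride + 1
    wout = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xpad = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                      constant_values=-np.inf)
    else:
        xpad = x.data
    cols = _im2col(xpad, kernel, kernel, stride, stride, hout, wout)
    cols = cols.reshape(b, c, kernel * kernel, hout, wout)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, arg[:, :, None], g[:, :, None], axis=2)
        dcols = dcols.reshape(b, c, kernel, kernel, hout, wout)
        dxpad = np.zeros_like(xpad)
        for i in range(kernel):
            for j in range(kernel):
                dxpad[:, :, i:i + stride * hout:stride,
                      j:j + stride * wout:stride] += dcols[:, :, i, j]
        if padding:
            dxpad = dxpad[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(dxpad.astype(np.float32))

    return Tensor._make(out.astype(np.float32), (x,), bw)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def bw(g):
        gr = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accumulate(gr.astype(np.float32))

    return Tensor._make(out, (x,), bw)


def resize_nearest(x: Tensor, out_hw: tuple) -> Tensor:
    """Nearest-neighbour resize to an arbitrary (H, W)."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return x * 1.0
    ri = (np.arange(ho) * h // ho).astype(np.intp)
    ci = (np.arange(wo) * w // wo).astype(np.intp)
    out = x.data[:, :, ri[:, None], ci[None, :]]

    def bw(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
        x._accumulate(dx)

    return Tensor._make(out, (x,), bw)


def adaptive_avg_pool_1(x: Tensor) -> Tensor:
    """Global average pool to 1x1 (keepdims)."""
    return x.mean(axis=(2, 3), keepdims=True)


def pad_replicate2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Edge-replicate padding on the two spatial axes (differentiable).

    Unlike zero padding this preserves constant inputs, which keeps
    normalised attention gates exactly flat on flat features.
    """
    from .tensor import concat as _concat
    if ph:
        top = _concat([x[:, :, 0:1]] * ph, axis=2) if ph > 1 else x[:, :, 0:1]
        bot_sl = x[:, :, x.shape[2] - 1:x.shape[2]]
        bot = _concat([bot_sl] * ph, axis=2) if ph > 1 else bot_sl
        x = _concat([top, x, bot], axis=2)
    if pw:
        left_sl = x[:, :, :, 0:1]
        left = _concat([left_sl] * pw, axis=3) if pw > 1 else left_sl
        right_sl = x[:, :, :, x.shape[3] - 1:x.shape[3]]
        right = _concat([right_sl] * pw, axis=3) if pw > 1 else right_sl
        x = _concat([left, x, right], axis=3)
    return x


# ---------------------------------------------------------------------------
# bilinear sampling (deformable convolution support)
# ---------------------------------------------------------------------------

def bilinear_gather(x: Tensor, ys: np.ndarray, xs: np.ndarray) -> Tensor:
    """Sample ``x`` [B,C,H,W] at fractional coords ``ys/xs`` [B,K,L].

    Out-of-bounds samples read as zero.  Gradients flow to ``x`` only;
    the coordinate arrays are plain NumPy (treated as constants).
    Returns [B, C, K, L].
    """
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    wy = (ys - y0).astype(np.float32)
    wx = (xs - x0).astype(np.float32)

    corners = []
    for dy, dx_, wgt in ((0, 0, (1 - wy) * (1 - wx)), (0, 1, (1 - wy) * wx),
                         (1, 0, wy * (1 - wx)), (1, 1, wy * wx)):
        yi, xi = y0 + dy, x0 + dx_
        valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
        yc = np.clip(yi, 0, h - 1)
        xc = np.clip(xi, 0, w - 1)
        corners.append((yc, xc, (wgt * valid).astype(np.float32)))

    bidx = np.arange(b)[:, None, None]
    out = np.zeros((b, c) + ys.shape[1:], dtype=np.float32)
    for yc, xc, wgt in corners:
        out += x.data[bidx, :, yc, xc].transpose(0, 3, 1, 2) * wgt[:, None]

    def bw(g):
        dx = np.zeros_like(x.data)
        for yc, xc, wgt in corners:
            contrib = (g * wgt[:, None]).transpose(0, 2, 3, 1)  # [B,K,L,C]
            np.add.at(dx, (bidx, slice(None), yc, xc), contrib)
        x._accumulate(dx)

    return Tensor._make(out, (x,), bw)
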