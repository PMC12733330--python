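"""Convolution primitives (im2col based) for the autograd engine.

``conv2d``'s input-vjp is ``conv_transpose2d`` and vice versa, and each
weight-vjp is its own primitive, so a second backward pass (needed by the
gradient penalty, which differentiates an input-gradient w.r.t. the
weights) only ever requires vjps that are implemented here.  Weight-grad
primitives appear only as terminal nodes of that second pass and therefore
carry no vjps of their own.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make, as_tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d"]


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C, kh, kw, Ho, Wo) patch view materialised as array."""
    B, C, H, W = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(B, C, kh, kw, Ho, Wo),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw), writeable=False)
    return np.ascontiguousarray(view)


def _col2im(cols: np.ndarray, H: int, W: int, sh: int, sw: int, ph: int, pw: int) -> np.ndarray:
    """Inverse scatter-add of :func:`_im2col`; cols is (B,C,kh,kw,Ho,Wo)."""
    B, C, kh, kw, Ho, Wo = cols.shape
    out = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        hi = i + sh * Ho
        for j in range(kw):
            wj = j + sw * Wo
            out[:, :, i:hi:sh, j:wj:sw] += cols[:, :, i, j]
    if ph or pw:
        out = out[:, :, ph:ph + H, pw:pw + W]
    return out


def _conv2d_data(x, w, stride, padding, groups):
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    Co, Cin_g, kh, kw = w.shape
    B, C, H, W = x.shape
    if C != Cin_g * groups or Co % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {w.shape}, groups {groups}")
    cols = _im2col(x, kh, kw, sh, sw, ph, pw)
    Ho, Wo = cols.shape[4], cols.shape[5]
    # (B, G, Cg*kh*kw, L) x (G, Og, Cg*kh*kw)
    cols = cols.reshape(B, groups, Cin_g * kh * kw, Ho * Wo)
    wm = w.reshape(groups, Co // groups, Cin_g * kh * kw)
    out = np.matmul(wm[None], cols)  # (B, G, Og, L)
    return out.reshape(B, Co, Ho, Wo)


def _conv_transpose2d_data(x, w, stride, padding, output_padding, groups):
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    oh, ow = _pair(output_padding)
    Cin, Cout_g, kh, kw = w.shape
    B, C, H, W = x.shape
    if C != Cin:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {w.shape}")
    Ho = (H - 1) * sh - 2 * ph + kh + oh
    Wo = (W - 1) * sw - 2 * pw + kw + ow
    xm = x.reshape(B, groups, Cin // groups, H * W)
    wm = w.reshape(groups, Cin // groups, Cout_g * kh * kw)
    cols = np.matmul(wm.transpose(0, 2, 1)[None], xm)  # (B,G,Og*kh*kw,L)
    cols = cols.reshape(B, groups * Cout_g, kh, kw, H, W)
    # col2im over an output grid of (Ho+2p) x (Wo+2p) before cropping
    return _col2im_t(cols, Ho, Wo, sh, sw, ph, pw)


def _col2im_t(cols, Ho, Wo, sh, sw, ph, pw):
    B, C, kh, kw, H, W = cols.shape
    out = np.zeros((B, C, Ho + 2 * ph, Wo + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * H:sh, j:j + sw * W:sw] += cols[:, :, i, j]
    if ph or pw:
        out = out[:, :, ph:ph + Ho, pw:pw + Wo]
    return out


def _conv2d_wgrad_data(x, g, kh, kw, stride, padding, groups):
    """d(conv2d)/d(weight): correlate input patches with the output grad."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    Bo, Co, Ho, Wo = g.shape
    cols = _im2col(x, kh, kw, sh, sw, ph, pw)[:, :, :, :, :Ho, :Wo]
    Cin_g = C // groups
    cols = cols.reshape(B, groups, Cin_g * kh * kw, Ho * Wo)
    gm = g.reshape(B, groups, Co // groups, Ho * Wo)
    out = np.matmul(gm, cols.transpose(0, 1, 3, 2)).sum(axis=0)  # (G,Og,K)
    return out.reshape(Co, Cin_g, kh, kw)


def _convT_wgrad_data(x, g, kh, kw, stride, padding, groups):
    """d(conv_transpose2d)/d(weight): weight shape (Cin, Cout_g, kh, kw)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, Cin, H, W = x.shape
    Bo, Cout, Ho, Wo = g.shape
    gcols = _im2col(g, kh, kw, sh, sw, ph, pw)[:, :, :, :, :H, :W]
    Cout_g = Cout // groups
    gcols = gcols.reshape(B, groups, Cout_g * kh * kw, H * W)
    xm = x.reshape(B, groups, Cin // groups, H * W)
    out = np.matmul(xm, gcols.transpose(0, 1, 3, 2)).sum(axis=0)  # (G, Cin_g, Og*kh*kw)
    return out.reshape(Cin, Cout_g, kh, kw)


def _no_vjp(*_a, **_k):  # pragma: no cover - guarded by construction
    raise NotImplementedError("third-order derivatives are not supported")


def conv2d(x, w, stride=1, padding=0, groups: int = 1) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    out_data = _conv2d_data(x.data, w.data, stride, padding, groups)
    H, W = x.shape[2], x.shape[3]
    Ho, Wo = out_data.shape[2], out_data.shape[3]
    kh, kw = w.shape[2], w.shape[3]
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    opad = (H - ((Ho - 1) * sh - 2 * ph + kh), W - ((Wo - 1) * sw - 2 * pw + kw))

    def vjp_x(g):
        return conv_transpose2d(g, w, stride=stride, padding=padding,
                                output_padding=opad, groups=groups)

    def vjp_w(g):
        return _conv2d_wgrad(x, g, kh, kw, stride, padding, groups)

    return _make(out_data, (x, w), (vjp_x, vjp_w))


def conv_transpose2d(x, w, stride=1, padding=0, output_padding=0, groups: int = 1) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    out_data = _conv_transpose2d_data(x.data, w.data, stride, padding, output_padding, groups)
    kh, kw = w.shape[2], w.shape[3]

    def vjp_x(g):
        return conv2d(g, w, stride=stride, padding=padding, groups=groups)

    def vjp_w(g):
        return _convT_wgrad(x, g, kh, kw, stride, padding, groups)

    return _make(out_data, (x, w), (vjp_x, vjp_w))


def _conv2d_wgrad(x, g, kh, kw, stride, padding, groups) -> Tensor:
    x, g = as_tensor(x), as_tensor(g)
    out = _conv2d_wgrad_data(x.data, g.data, kh, kw, stride, padding, groups)
    return _make(out, (x, g), (_no_vjp, _no_vjp))


def _convT_wgrad(x, g, kh, kw, stride, padding, groups) -> Tensor:
    x, g = as_tensor(x), as_tensor(g)
    out = _convT_wgrad_data(x.data, g.data, kh, kw, stride, padding, groups)
    return _make(out, (x, g), (_no_vjp, _no_vjp))


def max_pool2d(x, kernel_size, stride=None, padding=0) -> Tensor:
    """Max pooling with a first-order vjp (scatter to argmax positions)."""
    x = as_tensor(x)
    kh, kw = _pair(kernel_size)
    sh, sw = _pair(stride if stride is not None else kernel_size)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                    constant_values=-np.inf)
    cols = _im2col(xd, kh, kw, sh, sw, 0, 0)  # (B,C,kh,kw,Ho,Wo)
    Bc, Cc, _, _, Ho, Wo = cols.shape
    flat = cols.reshape(B, C, kh * kw, Ho, Wo)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def vjp(g):
        from .tensor import reshape as t_reshape, scatter_like
        gflat = t_reshape(g, (B * C * Ho * Wo,))
        # linear index of each max within the padded input
        ki, kj = np.unravel_index(arg, (kh, kw))
        oy = np.arange(Ho)[None, None, :, None] * sh
        ox = np.arange(Wo)[None, None, None, :] * sw
        iy = (oy + ki)
        ix = (ox + kj)
        Hp, Wp = H + 2 * ph, W + 2 * pw
        bidx = np.arange(B)[:, None, None, None]
        cidx = np.arange(C)[None, :, None, None]
        lin = (((bidx * C + cidx) * Hp + iy) * Wp + ix).reshape(-1)
        gpad = scatter_like(gflat, (B * C * Hp * Wp,), (lin,))
        gpad = t_reshape(gpad, (B, C, Hp, Wp))
        if ph or pw:
            gpad = gpad[:, :, ph:ph + H, pw:pw + W]
        return gpad

    return _make(out_data, (x,), (vjp,))
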