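"""Neural-network layers built on the autograd engine.

Each layer knows how to run forward, report its trainable parameter count,
and report the multiply-accumulate (MAC) cost of a forward pass at a given
input shape.  The MAC convention counts convolution and linear layers only
(``k_h * k_w * C_in/groups * C_out * H_out * W_out`` and ``in * out``);
normalisation, activations and pooling are free.  That is the convention
under which published "FLOPs (G)" tables for image classifiers are
reproduced.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .conv import conv2d, conv_transpose2d
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvTranspose2d", "Linear",
    "BatchNorm2d", "InstanceNorm2d", "GroupNorm", "Dropout",
    "ReLU", "LeakyReLU", "GELU", "Tanh", "Sigmoid",
    "GlobalAvgPool", "AvgPool2d", "Flatten",
]


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


class Module:
    """Minimal container: tracks sub-modules and parameters by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif name in self._buffers:
            self._buffers[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out["buffer:" + name] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
        for name, _ in list(self.named_buffers()):
            key = "buffer:" + name
            if key in state:
                self._set_buffer(name, np.asarray(state[key]))

    def _set_buffer(self, dotted: str, value: np.ndarray):
        mod = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        setattr(mod, parts[-1], value)

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- accounting ----------------------------------------------------------
    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def macs(self, in_shape) -> int:
        """Total MACs for one forward pass at ``in_shape`` (C, H, W)."""
        total, _ = self._walk_macs(tuple(in_shape))
        return total

    def _walk_macs(self, in_shape):
        total = 0
        shape = in_shape
        for m in self._modules.values():
            sub, shape = m._walk_macs(shape)
            total += sub
        return total, shape


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_std(fan_in: int) -> float:
    return math.sqrt(2.0 / fan_in)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        kh, kw = _pair(kernel_size)
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kh * kw
        w = rng.normal(0.0, _he_std(fan_in), (out_channels, in_channels // groups, kh, kw))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)

    def forward(self, x):
        out = conv2d(x, self.weight, stride=self.stride, padding=self.padding,
                     groups=self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out

    def out_shape(self, in_shape):
        c, h, w = in_shape
        kh, kw = self.kernel_size
        sh, sw = _pair(self.stride)
        ph, pw = _pair(self.padding)
        return (self.out_channels, (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1)

    def _walk_macs(self, in_shape):
        out = self.out_shape(in_shape)
        kh, kw = self.kernel_size
        macs = kh * kw * (self.in_channels // self.groups) * self.out_channels * out[1] * out[2]
        return macs, out


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, output_padding=0, groups=1, bias=True, rng=None,
                 dtype=np.float32):
        super().__init__()
        kh, kw = _pair(kernel_size)
        rng = rng or np.random.default_rng(0)
        fan_in = (out_channels // groups) * kh * kw
        w = rng.normal(0.0, _he_std(fan_in), (in_channels, out_channels // groups, kh, kw))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.groups = groups
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)

    def forward(self, x):
        out = conv_transpose2d(x, self.weight, stride=self.stride,
                               padding=self.padding,
                               output_padding=self.output_padding,
                               groups=self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out

    def out_shape(self, in_shape):
        c, h, w = in_shape
        kh, kw = self.kernel_size
        sh, sw = _pair(self.stride)
        ph, pw = _pair(self.padding)
        oh, ow = _pair(self.output_padding)
        return (self.out_channels,
                (h - 1) * sh - 2 * ph + kh + oh,
                (w - 1) * sw - 2 * pw + kw + ow)

    def _walk_macs(self, in_shape):
        out = self.out_shape(in_shape)
        kh, kw = self.kernel_size
        # same kernel-tap count as the matching forward convolution
        macs = kh * kw * (self.out_channels // self.groups) * self.in_channels \
            * in_shape[1] * in_shape[2]
        return macs, out


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, _he_std(in_features), (in_features, out_features))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True) if bias else None
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def _walk_macs(self, in_shape):
        return self.in_features * self.out_features, (self.out_features,)


class _Norm(Module):
    def __init__(self, num_channels, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(num_channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, dtype=dtype), requires_grad=True)
        self.eps = eps
        self.num_channels = num_channels

    def _affine(self, xhat):
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)

    def _walk_macs(self, in_shape):
        return 0, in_shape


class BatchNorm2d(_Norm):
    def __init__(self, num_channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__(num_channels, eps, dtype)
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(num_channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(num_channels, dtype=np.float64))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = centered / T.sqrt(var + self.eps)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1).astype(x.dtype))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1).astype(x.dtype))
            xhat = (x - mu) / T.sqrt(var + self.eps)
        return self._affine(xhat)


class InstanceNorm2d(_Norm):
    """Per-sample normalisation; drop-in for BatchNorm in the critic."""

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        return self._affine(centered / T.sqrt(var + self.eps))


class GroupNorm(_Norm):
    def __init__(self, num_groups, num_channels, eps=1e-5, dtype=np.float32):
        super().__init__(num_channels, eps, dtype)
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups

    def forward(self, x):
        B, C, H, W = x.shape
        g = self.num_groups
        xg = x.reshape((B, g, C // g, H, W))
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=(2, 3, 4), keepdims=True)
        xhat = (centered / T.sqrt(var + self.eps)).reshape((B, C, H, W))
        return self._affine(xhat)


class Dropout(Module):
    def __init__(self, p=0.5, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)

    def _walk_macs(self, in_shape):
        return 0, in_shape


class _Activation(Module):
    def _walk_macs(self, in_shape):
        return 0, in_shape


class ReLU(_Activation):
    def forward(self, x):
        return T.relu(x)


class LeakyReLU(_Activation):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return T.leaky_relu(x, self.slope)


class GELU(_Activation):
    def forward(self, x):
        return T.gelu(x)


class Tanh(_Activation):
    def forward(self, x):
        return T.tanh(x)


class Sigmoid(_Activation):
    def forward(self, x):
        return T.sigmoid(x)


class GlobalAvgPool(_Activation):
    """(B,C,H,W) -> (B,C) global average pooling."""

    def forward(self, x):
        return x.mean(axis=(2, 3))

    def _walk_macs(self, in_shape):
        return 0, (in_shape[0],)


class AvgPool2d(_Activation):
    """Average pooling by integer factor (input size must divide evenly)."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return avg_pool2d(x, self.factor)

    def _walk_macs(self, in_shape):
        c, h, w = in_shape
        return 0, (c, h // self.factor, w // self.factor)


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    B, C, H, W = x.shape
    if H % factor or W % factor:
        raise ValueError(f"spatial size {(H, W)} not divisible by pool factor {factor}")
    xr = x.reshape((B, C, H // factor, factor, W // factor, factor))
    return xr.mean(axis=(3, 5))


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    H = x.shape[2]
    if H == out_size:
        return x
    if H % out_size:
        raise ValueError(f"adaptive pool requires divisibility, got {H} -> {out_size}")
    return avg_pool2d(x, H // out_size)


class Flatten(_Activation):
    def forward(self, x):
        return x.reshape((x.shape[0], -1))

    def _walk_macs(self, in_shape):
        n = 1
        for s in in_shape:
            n *= s
        return 0, (n,)
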