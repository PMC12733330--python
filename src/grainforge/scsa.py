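"""Spatial-Channel Synergistic Attention (SCSA).

Two serially composed halves:

* **SMSA** (shareable multi-semantic spatial attention): the feature map
  is pooled along each spatial axis, the channel dimension is split into
  groups, each group passes through a depthwise 1-D convolution with a
  group-specific kernel size (multi-scale), and the group-normalised,
  sigmoid-gated results reweight the input along both axes.

* **PCSA** (progressive channel self-attention): the map is average-pooled
  to a small spatial grid, depthwise convolutions produce per-channel
  query/key/value sequences, a single-head channel-by-channel attention
  (softmax over channels of ``Q K^T / sqrt(d)``) reweights the values, and
  the result - pooled to one pixel and sigmoid-gated - rescales every
  channel of the input.

Both halves are shape preserving, and both act purely as multiplicative
gates in (0, 1), so attention can attenuate but never amplify a feature.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor


@dataclasses.dataclass(frozen=True)
class SMSAConfig:
    n_groups: int = 4
    kernel_sizes: tuple = (3, 5, 7, 9)

    def __post_init__(self):
        if len(self.kernel_sizes) != self.n_groups:
            raise ValueError("need one kernel size per group")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")


@dataclasses.dataclass(frozen=True)
class PCSAConfig:
    pooled_size: int = 7
    qkv_kernel: int = 3


class SMSA(nn.Module):
    """Multi-scale spatial gate over H- and W-pooled channel sequences.

    One depthwise 1-D convolution per channel group, shared between the
    two pooling directions.
    """

    def __init__(self, channels: int, cfg: SMSAConfig = SMSAConfig(), rng=None,
                 dtype=np.float32):
        super().__init__()
        if channels % cfg.n_groups:
            raise ValueError(
                f"channels ({channels}) must divide into {cfg.n_groups} groups")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.channels = channels
        cg = channels // cfg.n_groups
        self.group_channels = cg
        for i, k in enumerate(cfg.kernel_sizes):
            conv = nn.Conv2d(cg, cg, (1, k), padding=(0, k // 2), groups=cg,
                             bias=False, rng=rng, dtype=dtype)
            setattr(self, f"conv{i}", conv)
        self.norm_h = nn.GroupNorm(cfg.n_groups, channels, dtype=dtype)
        self.norm_w = nn.GroupNorm(cfg.n_groups, channels, dtype=dtype)

    def _direction_gate(self, seq: Tensor, norm: nn.GroupNorm) -> Tensor:
        # seq: (B, C, L) pooled sequence; returns sigmoid gate (B, C, L)
        B, C, L = seq.shape
        cg = self.group_channels
        outs = []
        for i in range(self.cfg.n_groups):
            part = seq[:, i * cg:(i + 1) * cg, :].reshape((B, cg, 1, L))
            conv = getattr(self, f"conv{i}")
            outs.append(conv(part).reshape((B, cg, L)))
        mixed = nn.concat(outs, axis=1).reshape((B, C, 1, L))
        return nn.sigmoid(norm(mixed)).reshape((B, C, L))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        seq_h = x.mean(axis=3)           # (B, C, H)
        seq_w = x.mean(axis=2)           # (B, C, W)
        gate_h = self._direction_gate(seq_h, self.norm_h).reshape((B, C, H, 1))
        gate_w = self._direction_gate(seq_w, self.norm_w).reshape((B, C, 1, W))
        return x * gate_h * gate_w

    def _walk_macs(self, in_shape):
        return 0, in_shape  # negligible 1-D convolutions on pooled sequences


class PCSA(nn.Module):
    """Compressed single-head channel self-attention gate."""

    def __init__(self, channels: int, cfg: PCSAConfig = PCSAConfig(), rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.channels = channels
        k = cfg.qkv_kernel
        for name in ("q", "k", "v"):
            conv = nn.Conv2d(channels, channels, (1, k), padding=(0, k // 2),
                             groups=channels, bias=False, rng=rng, dtype=dtype)
            setattr(self, f"proj_{name}", conv)

    def attention(self, x: Tensor):
        """Return (attention matrix (B,C,C), value (B,C,d)) on the pooled map."""
        B, C, H, W = x.shape
        p = min(self.cfg.pooled_size, H, W)
        while H % p or W % p:  # largest compression grid that tiles the map
            p -= 1
        pooled = nn.adaptive_avg_pool2d(x, p)            # (B, C, p, p)
        d = p * p
        flat = pooled.reshape((B, C, 1, d))
        q = self.proj_q(flat).reshape((B, C, d))
        k = self.proj_k(flat).reshape((B, C, d))
        v = self.proj_v(flat).reshape((B, C, d))
        scores = (q @ nn.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(d))
        attn = nn.softmax(scores, axis=-1)               # rows sum to 1 over channels
        return attn, v

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        attn, v = self.attention(x)
        mixed = attn @ v                                  # (B, C, d)
        gate = nn.sigmoid(mixed.mean(axis=2))             # pool to one pixel
        return x * gate.reshape((B, C, 1, 1))

    def _walk_macs(self, in_shape):
        return 0, in_shape


class SCSA(nn.Module):
    """Serial composition: spatial gate (SMSA) then channel gate (PCSA)."""

    def __init__(self, channels: int, smsa_cfg: SMSAConfig = SMSAConfig(),
                 pcsa_cfg: PCSAConfig = PCSAConfig(), rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.smsa = SMSA(channels, smsa_cfg, rng=rng, dtype=dtype)
        self.pcsa = PCSA(channels, pcsa_cfg, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.pcsa(self.smsa(x))

    def _walk_macs(self, in_shape):
        return 0, in_shape


def smsa_forward(x, channels=None, cfg: SMSAConfig = SMSAConfig(), rng=None):
    """Functional wrapper: build an SMSA for ``x`` and apply it."""
    x = nn.as_tensor(x)
    mod = SMSA(channels or x.shape[1], cfg, rng=rng, dtype=x.dtype)
    return mod(x)


def pcsa_forward(x, channels=None, cfg: PCSAConfig = PCSAConfig(), rng=None):
    x = nn.as_tensor(x)
    mod = PCSA(channels or x.shape[1], cfg, rng=rng, dtype=x.dtype)
    return mod(x)
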