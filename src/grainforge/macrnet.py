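"""MACRNet: multi-branch asymmetric depthwise-separable residual classifier.

Architecture: a 7x7 stride-2 stem (224x224x3 -> 112x112x64), four feature
stages built from MACR residual blocks, global average pooling to a
1024-long feature, dropout and a linear head.

Each MACR block runs five parallel branches - a 1x1 pointwise branch and,
for k in {3,5,7,9}, a depthwise-separable asymmetric branch (pointwise
expansion, depthwise k x 1 then 1 x k, pointwise projection).  Branch
outputs are concatenated on channels (their widths sum to the block's
output channels), batch-normalised, passed through GELU and added to the
residual input.  Three residual flavours:

* maintaining  (block1): identity skip, shape preserved;
* convolutional: stride 1 but channels change, 1x1-projection skip
  (used at the entry of stage 1, 64 -> 128 at 112x112);
* downsampling (block2): stride 2, channels double, strided 1x1 skip.

The published compute budget (8.446 M parameters, 4.542 G MACs at
224x224) fixes neither the stage depths nor the branches' internal
widths, so :func:`calibrate_config` recovers them by a deterministic
exhaustive search over stage depths and a hidden-width multiplier; the
result is frozen as the reference configuration.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import pathlib
from typing import Sequence

import numpy as np
import yaml

from . import nn
from .nn import Tensor

ASYMMETRIC_KERNELS = (3, 5, 7, 9)
ALL_KERNELS = (1,) + ASYMMETRIC_KERNELS

#: Published compute budget used by the calibration search.
TARGET_PARAMS = 8.446e6
TARGET_MACS = 4.542e9


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MACRNetConfig:
    image_size: int = 224
    stem_channels: int = 64
    stage_channels: tuple = (128, 256, 512, 1024)
    stage_depths: tuple = (2, 2, 2, 2)
    #: hidden-width multiplier for the asymmetric branches' depthwise pair
    width_multiplier: float = 1.0
    branch_kernels: tuple = ALL_KERNELS
    n_classes: int = 6
    dropout: float = 0.2

    def __post_init__(self):
        if len(self.stage_depths) != len(self.stage_channels):
            raise ConfigurationError("one depth per stage required")
        if any(d < 1 for d in self.stage_depths):
            raise ConfigurationError("stage depths must be >= 1")
        if 1 not in self.branch_kernels:
            raise ConfigurationError("the 1x1 branch is always present")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "MACRNetConfig":
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)


def smoke_config() -> MACRNetConfig:
    """Tiny configuration for CPU smoke training on 32x32 inputs."""
    return MACRNetConfig(image_size=32, stem_channels=16,
                         stage_channels=(24, 48, 48, 64),
                         stage_depths=(1, 1, 1, 1), width_multiplier=0.5)


# ---------------------------------------------------------------------------
# widths
# ---------------------------------------------------------------------------

def branch_widths(out_channels: int, kernels: Sequence[int] = ALL_KERNELS) -> dict:
    """Output width per branch; widths always sum to ``out_channels``.

    Full kernel set: the 1x1 branch takes one third, the four asymmetric
    branches share the remainder equally, rounding remainder to the 1x1
    branch.  When an asymmetric branch has been removed its width is
    redistributed proportionally over the survivors.
    """
    full = {}
    base1 = out_channels // 3
    rem = out_channels - base1
    wk = rem // len(ASYMMETRIC_KERNELS)
    full[1] = base1 + (rem - wk * len(ASYMMETRIC_KERNELS))
    for k in ASYMMETRIC_KERNELS:
        full[k] = wk
    kernels = tuple(kernels)
    if set(kernels) == set(ALL_KERNELS):
        return full
    kept_total = sum(full[k] for k in kernels)
    widths = {k: int(full[k] * out_channels / kept_total) for k in kernels}
    widths[1] += out_channels - sum(widths.values())  # rounding remainder
    return widths


def _hidden_width(width: int, multiplier: float) -> int:
    return max(4, int(round(multiplier * width)))


# ---------------------------------------------------------------------------
# layer enumeration (shared by the model builder and the analytic counters)
# ---------------------------------------------------------------------------

def _block_layers(in_ch: int, out_ch: int, stride: int, kernels, multiplier,
                  in_hw: int):
    """Yield (kind, spec-dict) for every conv/BN layer of one MACR block.

    ``kind`` is "conv" with keys (cin, cout, kh, kw, stride, groups, h, w)
    where h, w are the *output* spatial size, or "bn"/"skip".
    """
    out_hw = in_hw // stride
    widths = branch_widths(out_ch, kernels)
    for k in sorted(widths):
        w = widths[k]
        if k == 1:
            yield ("conv", dict(cin=in_ch, cout=w, kh=1, kw=1, stride=stride,
                                groups=1, h=out_hw, w_=out_hw))
        else:
            h_ch = _hidden_width(w, multiplier)
            yield ("conv", dict(cin=in_ch, cout=h_ch, kh=1, kw=1, stride=1,
                                groups=1, h=in_hw, w_=in_hw))
            yield ("conv", dict(cin=h_ch, cout=h_ch, kh=k, kw=1, stride=stride,
                                groups=h_ch, h=out_hw, w_=in_hw))
            yield ("conv", dict(cin=h_ch, cout=h_ch, kh=1, kw=k, stride=stride,
                                groups=h_ch, h=out_hw, w_=out_hw))
            yield ("conv", dict(cin=h_ch, cout=w, kh=1, kw=1, stride=1,
                                groups=1, h=out_hw, w_=out_hw))
    yield ("bn", dict(channels=out_ch))
    if stride != 1 or in_ch != out_ch:
        yield ("conv", dict(cin=in_ch, cout=out_ch, kh=1, kw=1, stride=stride,
                            groups=1, h=out_hw, w_=out_hw))


def _network_layers(cfg: MACRNetConfig):
    """Enumerate every parameterised layer of the whole network."""
    hw = cfg.image_size // 2
    yield ("conv", dict(cin=3, cout=cfg.stem_channels, kh=7, kw=7, stride=2,
                        groups=1, h=hw, w_=hw))
    yield ("bn", dict(channels=cfg.stem_channels))
    in_ch = cfg.stem_channels
    for s, (out_ch, depth) in enumerate(zip(cfg.stage_channels, cfg.stage_depths)):
        stride = 1 if s == 0 else 2
        yield from _block_layers(in_ch, out_ch, stride, cfg.branch_kernels,
                                 cfg.width_multiplier, hw)
        hw //= stride
        for _ in range(depth - 1):
            yield from _block_layers(out_ch, out_ch, 1, cfg.branch_kernels,
                                     cfg.width_multiplier, hw)
        in_ch = out_ch
    yield ("linear", dict(cin=in_ch, cout=cfg.n_classes))


def config_param_count(cfg: MACRNetConfig) -> int:
    """Trainable parameters, computed arithmetically from the config."""
    total = 0
    for kind, d in _network_layers(cfg):
        if kind == "conv":
            total += d["kh"] * d["kw"] * (d["cin"] // d["groups"]) * d["cout"]
        elif kind == "bn":
            total += 2 * d["channels"]
        else:
            total += d["cin"] * d["cout"] + d["cout"]
    return total


def config_mac_count(cfg: MACRNetConfig) -> int:
    """Forward-pass MACs (conv + linear convention) from the config."""
    total = 0
    for kind, d in _network_layers(cfg):
        if kind == "conv":
            total += (d["kh"] * d["kw"] * (d["cin"] // d["groups"]) * d["cout"]
                      * d["h"] * d["w_"])
        elif kind == "linear":
            total += d["cin"] * d["cout"]
    return total


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MACRBlock(nn.Module):
    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 kernels: Sequence[int] = ALL_KERNELS, multiplier: float = 1.0,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.stride = stride
        self.kernels = tuple(sorted(kernels))
        widths = branch_widths(out_channels, kernels)
        self.widths = widths
        for k in self.kernels:
            w = widths[k]
            if k == 1:
                branch = nn.Sequential(
                    nn.Conv2d(in_channels, w, 1, stride=stride, bias=False,
                              rng=rng, dtype=dtype))
            else:
                h = _hidden_width(w, multiplier)
                branch = nn.Sequential(
                    nn.Conv2d(in_channels, h, 1, bias=False, rng=rng, dtype=dtype),
                    nn.Conv2d(h, h, (k, 1), stride=(stride, 1),
                              padding=(k // 2, 0), groups=h, bias=False,
                              rng=rng, dtype=dtype),
                    nn.Conv2d(h, h, (1, k), stride=(1, stride),
                              padding=(0, k // 2), groups=h, bias=False,
                              rng=rng, dtype=dtype),
                    nn.Conv2d(h, w, 1, bias=False, rng=rng, dtype=dtype))
            setattr(self, f"branch{k}", branch)
        self.bn = nn.BatchNorm2d(out_channels, dtype=dtype)
        self.act = nn.GELU()
        if stride != 1 or in_channels != out_channels:
            self.skip = nn.Conv2d(in_channels, out_channels, 1, stride=stride,
                                  bias=False, rng=rng, dtype=dtype)
        else:
            self.skip = None

    @property
    def block_type(self) -> str:
        if self.stride != 1:
            return "downsampling"
        return "maintaining" if self.skip is None else "convolutional"

    def forward(self, x):
        outs = [getattr(self, f"branch{k}")(x) for k in self.kernels]
        main = self.act(self.bn(nn.concat(outs, axis=1)))
        identity = x if self.skip is None else self.skip(x)
        return identity + main

    def _walk_macs(self, in_shape):
        c, hh, ww = in_shape
        total = 0
        for k in self.kernels:
            m, _ = getattr(self, f"branch{k}")._walk_macs(in_shape)
            total += m
        if self.skip is not None:
            m, _ = self.skip._walk_macs(in_shape)
            total += m
        return total, (self.out_channels, hh // self.stride, ww // self.stride)


class MACRNet(nn.Module):
    def __init__(self, cfg: MACRNetConfig = MACRNetConfig(), rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.stem = nn.Sequential(
            nn.Conv2d(3, cfg.stem_channels, 7, stride=2, padding=3, bias=False,
                      rng=rng, dtype=dtype),
            nn.BatchNorm2d(cfg.stem_channels, dtype=dtype),
            nn.GELU())
        blocks = []
        in_ch = cfg.stem_channels
        for s, (out_ch, depth) in enumerate(zip(cfg.stage_channels, cfg.stage_depths)):
            stride = 1 if s == 0 else 2
            blocks.append(MACRBlock(in_ch, out_ch, stride, cfg.branch_kernels,
                                    cfg.width_multiplier, rng=rng, dtype=dtype))
            for _ in range(depth - 1):
                blocks.append(MACRBlock(out_ch, out_ch, 1, cfg.branch_kernels,
                                        cfg.width_multiplier, rng=rng, dtype=dtype))
            in_ch = out_ch
        self.stages = nn.Sequential(*blocks)
        self.pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(cfg.dropout,
                                  rng=np.random.default_rng(rng.integers(2 ** 31)))
        self.head = nn.Linear(in_ch, cfg.n_classes, rng=rng, dtype=dtype)

    def features(self, x):
        return self.pool(self.stages(self.stem(x)))

    def forward(self, x):
        return self.head(self.dropout(self.features(x)))


def build_macrnet(cfg: MACRNetConfig = MACRNetConfig(), seed: int = 0) -> MACRNet:
    return MACRNet(cfg, rng=np.random.default_rng(seed))


def remove_branch(cfg: MACRNetConfig, kernel_k: int) -> MACRNetConfig:
    """Ablation variant with one asymmetric branch deleted from every block."""
    if kernel_k not in ASYMMETRIC_KERNELS:
        raise ConfigurationError(
            f"only asymmetric branches {ASYMMETRIC_KERNELS} can be removed")
    kept = tuple(k for k in cfg.branch_kernels if k != kernel_k)
    return dataclasses.replace(cfg, branch_kernels=kept)


# ---------------------------------------------------------------------------
# counting (model-based)
# ---------------------------------------------------------------------------

def count_params(model: nn.Module) -> int:
    """Exact count of trainable scalars."""
    return model.param_count()

def count_macs(model: nn.Module, input_size: int = 224) -> int:
    """Multiply-accumulates for one forward pass (conv + linear only)."""
    return model.macs((3, input_size, input_size))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationResult:
    config: MACRNetConfig | None
    achieved_params: int
    achieved_macs: int
    rel_err_params: float
    rel_err_macs: float
    ok: bool


def calibrate_config(target_params: float = TARGET_PARAMS,
                     target_macs: float = TARGET_MACS,
                     tolerance: float = 0.01,
                     depth_range=range(1, 7),
                     multiplier_step: float = 0.001) -> CalibrationResult:
    """Deterministic exhaustive search for the reference configuration.

    For every stage-depth combination the parameter count is affine in the
    hidden-width multiplier, so the multiplier is solved for the parameter
    target and refined on a fixed grid; the combination minimising the
    maximum relative error against (params, MACs) wins.  Ties break toward
    the lexicographically smallest (depths, multiplier).
    """
    if target_params <= 0 or target_macs <= 0:
        raise ConfigurationError("targets must be positive")
    if not 0 < tolerance <= 0.05:
        raise ConfigurationError("tolerance must lie in (0, 0.05]")
    best = None
    for d1 in depth_range:
        for d2 in depth_range:
            for d3 in depth_range:
                for d4 in depth_range:
                    depths = (d1, d2, d3, d4)
                    cand = _best_multiplier(depths, target_params, target_macs,
                                            multiplier_step)
                    if cand is None:
                        continue
                    err, mult, p, m = cand
                    key = (err, depths, mult)
                    if best is None or key < best[0]:
                        cfg = MACRNetConfig(stage_depths=depths,
                                            width_multiplier=mult)
                        best = (key, cfg, p, m)
    if best is None:
        return CalibrationResult(None, 0, 0, float("inf"), float("inf"), False)
    _, cfg, p, m = best
    rp = abs(p - target_params) / target_params
    rm = abs(m - target_macs) / target_macs
    ok = max(rp, rm) <= tolerance
    return CalibrationResult(cfg, int(p), int(m), rp, rm, ok)


def _best_multiplier(depths, target_params, target_macs, step):
    base = MACRNetConfig(stage_depths=depths, width_multiplier=0.0)
    hi = MACRNetConfig(stage_depths=depths, width_multiplier=2.0)
    p0, p2 = config_param_count(base), config_param_count(hi)
    slope = (p2 - p0) / 2.0
    if slope <= 0:
        return None
    m_star = (target_params - p0) / slope
    if not 0.05 <= m_star <= 4.0:
        return None
    best = None
    lo = max(step, round(m_star - 0.02, 6))
    for i in range(int(lo / step), int((m_star + 0.02) / step) + 1):
        mult = round(i * step, 6)
        cfg = MACRNetConfig(stage_depths=depths, width_multiplier=mult)
        p = config_param_count(cfg)
        m = config_mac_count(cfg)
        err = max(abs(p - target_params) / target_params,
                  abs(m - target_macs) / target_macs)
        if best is None or err < best[0]:
            best = (err, mult, p, m)
    return best


def freeze_config(result: CalibrationResult, path) -> None:
    path = pathlib.Path(path)
    payload = {
        "config": result.config.to_dict(),
        "achieved_params": result.achieved_params,
        "achieved_macs": result.achieved_macs,
        "rel_err_params": float(result.rel_err_params),
        "rel_err_macs": float(result.rel_err_macs),
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_frozen_config(path=None) -> MACRNetConfig:
    """Load the frozen reference configuration (packaged by default)."""
    if path is None:
        ref = importlib.resources.files("grainforge.configs") / "macrnet_reference.yaml"
        text = ref.read_text()
    else:
        text = pathlib.Path(path).read_text()
    payload = yaml.safe_load(text)
    return MACRNetConfig.from_dict(payload["config"])


def reference_config() -> MACRNetConfig:
    return load_frozen_config()


# ---------------------------------------------------------------------------
# ResNet18 baseline (MAC-counter verification only)
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False,
                               rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(out_ch, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False,
                                  rng=rng, dtype=dtype)
            self.down_bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.down = None

    def forward(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        identity = x if self.down is None else self.down_bn(self.down(x))
        return nn.relu(identity + h)

    def _walk_macs(self, in_shape):
        m1, s1 = self.conv1._walk_macs(in_shape)
        m2, s2 = self.conv2._walk_macs(s1)
        total = m1 + m2
        if self.down is not None:
            md, _ = self.down._walk_macs(in_shape)
            total += md
        return total, s2


class _MaxPool(nn.Module):
    def __init__(self, kernel, stride, padding):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return nn.max_pool2d(x, self.kernel, self.stride, self.padding)

    def _walk_macs(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kernel) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel) // self.stride + 1
        return 0, (c, ho, wo)


class ResNet18(nn.Module):
    """Standard 18-layer residual classifier (the MAC-counter reference)."""

    def __init__(self, n_classes: int = 6, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False,
                               rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(64, dtype=dtype)
        self.maxpool = _MaxPool(3, 2, 1)
        layers = []
        in_ch = 64
        for out_ch, stride in ((64, 1), (64, 1), (128, 2), (128, 1),
                               (256, 2), (256, 1), (512, 2), (512, 1)):
            layers.append(_BasicBlock(in_ch, out_ch, stride, rng, dtype))
            in_ch = out_ch
        self.layers = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(512, n_classes, rng=rng, dtype=dtype)

    def forward(self, x):
        h = self.maxpool(nn.relu(self.bn1(self.conv1(x))))
        return self.fc(self.pool(self.layers(h)))


def build_resnet18(n_classes: int = 6, seed: int = 0) -> ResNet18:
    return ResNet18(n_classes, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# classifier training
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ClassifierTrainConfig:
    epochs: int = 120
    batch_size: int = 64
    lr: float = 1e-3
    lr_final: float = 1e-6
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-4
    seed: int = 0


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = nn.log_softmax(logits, axis=1)
    picked = logp[(np.arange(len(labels)), labels)]
    return -picked.mean()


def train_classifier(model: nn.Module, images: np.ndarray, labels: np.ndarray,
                     cfg: ClassifierTrainConfig = ClassifierTrainConfig(),
                     val_images: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None):
    """Adam + cosine-annealed LR cross-entropy training.

    ``images`` are normalised NCHW float32.  Returns (model, log) with the
    model carrying the weights of the best validation accuracy (training
    accuracy when no validation split is given).
    """
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                  weight_decay=cfg.weight_decay)
    n = len(images)
    bs = min(cfg.batch_size, n)
    log = []
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        opt.lr = nn.cosine_lr(cfg.lr, cfg.lr_final, epoch, cfg.epochs)
        perm = rng.permutation(n)
        model.train()
        tot_loss, tot_correct, seen = 0.0, 0, 0
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            xb = Tensor(images[idx])
            logits = model(xb)
            loss = cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += float(loss.data) * len(idx)
            tot_correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
            seen += len(idx)
        train_acc = tot_correct / seen
        entry = {"epoch": epoch, "lr": opt.lr, "train_loss": tot_loss / seen,
                 "train_acc": train_acc}
        if val_images is not None:
            val_acc, val_loss = evaluate_classifier(model, val_images, val_labels)
            entry.update(val_loss=val_loss, val_acc=val_acc)
            score = val_acc
        else:
            score = train_acc
        if score > best_acc:
            best_acc = score
            best_state = model.state_dict()
        log.append(entry)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def evaluate_classifier(model: nn.Module, images: np.ndarray,
                        labels: np.ndarray, batch_size: int = 64):
    """(accuracy, mean loss) in eval mode."""
    model.eval()
    correct, loss_sum = 0, 0.0
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            xb = Tensor(images[start:start + batch_size])
            yb = labels[start:start + batch_size]
            logits = model(xb)
            loss_sum += float(cross_entropy(logits, yb).data) * len(yb)
            correct += int((logits.data.argmax(axis=1) == yb).sum())
    model.train()
    return correct / len(images), loss_sum / len(images)


def predict(model: nn.Module, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    preds = []
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            preds.append(model(Tensor(images[start:start + batch_size])).data.argmax(axis=1))
    model.train()
    return np.concatenate(preds)


def to_model_input(images_hwc: np.ndarray, mean=(0.647, 0.638, 0.448),
                   std=(0.177, 0.192, 0.209)) -> np.ndarray:
    """[0,1] HWC image stack -> normalised NCHW float32."""
    x = (images_hwc - np.asarray(mean, dtype=np.float32)) / np.asarray(std, dtype=np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2).astype(np.float32))
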