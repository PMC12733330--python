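"""Wasserstein GAN with gradient penalty for kernel-image synthesis.

The generator maps a 100-d standard-normal latent through a dense
projection and a ladder of stride-2 transposed convolutions; two of the
upsampling stages are replaced by residual-attention (GSCSA) blocks that
wrap a spatial-channel synergistic attention module in a skip connection
before upsampling.  The critic is a fully convolutional six-stage
downsampler (3x3 kernels, stride 2, LeakyReLU 0.2) with a convolutional
scoring head and no fully connected layers; its scores are unbounded
reals, as the Wasserstein objective requires.

Losses (duality form):

    L_D = E[-D(x)] + E[D(G(z))] + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]
    L_G = -E[D(G(z))]

with xhat = eps*x + (1-eps)*G(z), eps ~ U[0,1] drawn once per sample.
Training alternates ``n_critic`` critic steps per generator step, Adam
betas (0.5, 0.999), fixed learning rates 1e-4 (G) / 2e-4 (D).  Weights
are checkpointed every 10 epochs and the record with the minimum FID
against the training distribution (under a pluggable embedder) is
selected.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Callable, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .scsa import SCSA, SMSAConfig, PCSAConfig


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    latent_dim: int = 100
    image_size: int = 224
    #: channel widths of the feature maps, starting at the dense 7x7 (or
    #: 4x4) projection and halving per 2x stage down to the 3-channel output.
    stage_channels: tuple = (512, 256, 128, 64, 32, 3)
    base_size: int = 7
    #: indices (into the upsampling stages) replaced by GSCSA blocks.
    gscsa_positions: tuple = (2, 3)

    def __post_init__(self):
        n_up = len(self.stage_channels) - 1
        if self.base_size * 2 ** n_up != self.image_size:
            raise ValueError("stage_channels ladder does not reach image_size")
        if self.stage_channels[-1] != 3:
            raise ValueError("output must have 3 channels")
        for p in self.gscsa_positions:
            if not 0 <= p < n_up:
                raise ValueError(f"gscsa position {p} out of range")


@dataclasses.dataclass(frozen=True)
class DiscriminatorConfig:
    image_size: int = 224
    stage_channels: tuple = (32, 64, 128, 256, 512, 512)
    leaky_slope: float = 0.2
    #: "batch" (paper-faithful), "instance", or "none"
    norm: str = "batch"

    def __post_init__(self):
        if len(self.stage_channels) != 6:
            raise ValueError("the critic has exactly six downsampling stages")


@dataclasses.dataclass(frozen=True)
class GanLossConfig:
    lambda_gp: float = 10.0
    n_critic: int = 5
    use_penalty: bool = True

    def __post_init__(self):
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be >= 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")


@dataclasses.dataclass(frozen=True)
class GanTrainConfig:
    epochs: int = 1600
    batch_size: int = 64
    lr_generator: float = 1e-4
    lr_discriminator: float = 2e-4
    betas: tuple = (0.5, 0.999)
    checkpoint_every: int = 10
    seed: int = 0


@dataclasses.dataclass
class CheckpointRecord:
    epoch: int
    fid_score: float
    state: dict


def smoke_generator_config(image_size: int = 64) -> GeneratorConfig:
    """Down-scaled generator for CPU smoke runs (4x4 base, narrow widths)."""
    n_up = int(np.log2(image_size // 4))
    if 4 * 2 ** n_up != image_size:
        raise ValueError("smoke image size must be 4 * a power of 2")
    widths = [64, 32, 16, 16, 16][:n_up] + [3]
    mid = max(1, n_up - 3)
    return GeneratorConfig(image_size=image_size, base_size=4,
                           stage_channels=tuple(widths),
                           gscsa_positions=(mid, mid + 1))


def smoke_discriminator_config(image_size: int = 64) -> DiscriminatorConfig:
    """Norm-free narrow critic for smoke runs.

    Batch/instance normalisation in the critic erases exactly the
    colour-statistic differences a small critic must score, so the smoke
    critic runs without normalisation.
    """
    return DiscriminatorConfig(image_size=image_size,
                               stage_channels=(8, 16, 16, 32, 32, 32),
                               norm="none")


def smoke_loss_config() -> GanLossConfig:
    """One critic step per generator step: at smoke scale (a handful of
    batches per epoch) the canonical 5:1 ratio starves the generator."""
    return GanLossConfig(n_critic=1)


def smoke_train_config(epochs: int = 20, batch_size: int = 16,
                       seed: int = 0) -> GanTrainConfig:
    """Smoke-scale optimisation: higher learning rates (keeping the 1:2
    generator:critic ratio) so ~10^2 updates produce visible convergence."""
    return GanTrainConfig(epochs=epochs, batch_size=batch_size, seed=seed,
                          lr_generator=1e-3, lr_discriminator=2e-3,
                          checkpoint_every=10)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class GSCSABlock(nn.Module):
    """Residual attention block followed by 2x transposed-conv upsampling.

    ``y = ReLU(BN(ConvT(x + SCSA(x))))`` - the skip keeps an identity
    gradient path around the attention gates.
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None,
                 dtype=np.float32, smsa_cfg: SMSAConfig = SMSAConfig(),
                 pcsa_cfg: PCSAConfig = PCSAConfig()):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.scsa = SCSA(in_channels, smsa_cfg, pcsa_cfg, rng=rng, dtype=dtype)
        self.up = nn.ConvTranspose2d(in_channels, out_channels, 4, stride=2,
                                     padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(out_channels, dtype=dtype)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.up(x + self.scsa(x))))


class _UpStage(nn.Module):
    def __init__(self, in_channels, out_channels, final: bool, rng, dtype):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_channels, out_channels, 4, stride=2,
                                     padding=1, bias=final, rng=rng, dtype=dtype)
        self.final = final
        if not final:
            self.bn = nn.BatchNorm2d(out_channels, dtype=dtype)
            self.act = nn.ReLU()

    def forward(self, x):
        x = self.up(x)
        if self.final:
            return nn.tanh(x)
        return self.act(self.bn(x))


class Generator(nn.Module):
    def __init__(self, cfg: GeneratorConfig = GeneratorConfig(), rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c0 = cfg.stage_channels[0]
        self.project = nn.Linear(cfg.latent_dim, c0 * cfg.base_size ** 2,
                                 rng=rng, dtype=dtype)
        self.project_bn = nn.BatchNorm2d(c0, dtype=dtype)
        n_up = len(cfg.stage_channels) - 1
        stages = []
        for i in range(n_up):
            cin, cout = cfg.stage_channels[i], cfg.stage_channels[i + 1]
            final = i == n_up - 1
            if i in cfg.gscsa_positions and not final:
                stages.append(GSCSABlock(cin, cout, rng=rng, dtype=dtype))
            else:
                stages.append(_UpStage(cin, cout, final, rng, dtype))
        self.stages = nn.Sequential(*stages)

    def forward(self, z: Tensor) -> Tensor:
        if z.ndim != 2 or z.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"latent batch must be (B, {self.cfg.latent_dim}), got {z.shape}")
        B = z.shape[0]
        c0, s = self.cfg.stage_channels[0], self.cfg.base_size
        x = self.project(z).reshape((B, c0, s, s))
        x = nn.relu(self.project_bn(x))
        return self.stages(x)


class Discriminator(nn.Module):
    """Fully convolutional critic: six stride-2 stages + conv scoring head."""

    def __init__(self, cfg: DiscriminatorConfig = DiscriminatorConfig(),
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        layers = []
        cin = 3
        for i, cout in enumerate(cfg.stage_channels):
            layers.append(nn.Conv2d(cin, cout, 3, stride=2, padding=1,
                                    bias=(cfg.norm == "none"), rng=rng, dtype=dtype))
            if cfg.norm == "batch" and i > 0:
                layers.append(nn.BatchNorm2d(cout, dtype=dtype))
            elif cfg.norm == "instance" and i > 0:
                layers.append(nn.InstanceNorm2d(cout, dtype=dtype))
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
            cin = cout
        self.features = nn.Sequential(*layers)
        self.score = nn.Conv2d(cin, 1, 3, stride=1, padding=1, bias=True,
                               rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W) images, got {x.shape}")
        h = self.features(x)
        s = self.score(h)
        return s.mean(axis=(1, 2, 3))  # one unbounded real per sample

    def n_downsampling_convs(self) -> int:
        return sum(1 for m in self.modules()
                   if isinstance(m, nn.Conv2d) and nn.layers._pair(m.stride)[0] == 2)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def gradient_penalty(critic: Callable[[Tensor], Tensor], x_real: Tensor,
                     x_fake: Tensor, lambda_gp: float = 10.0,
                     rng=None, eps_values: np.ndarray | None = None) -> Tensor:
    """``lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]`` at uniform interpolates.

    ``eps`` is drawn once per sample.  The norm runs over all input
    coordinates of each sample.  Returns a differentiable scalar so the
    penalty trains the critic (double backprop).
    """
    x_real, x_fake = nn.as_tensor(x_real), nn.as_tensor(x_fake)
    B = x_real.shape[0]
    if eps_values is None:
        rng = rng or np.random.default_rng(0)
        eps_values = rng.uniform(0.0, 1.0, size=B)
    eps = np.asarray(eps_values, dtype=x_real.dtype).reshape(B, 1, 1, 1)
    x_hat = Tensor(eps * x_real.data + (1 - eps) * x_fake.data, requires_grad=True)
    scores = critic(x_hat)
    (g,) = nn.grad(scores.sum(), [x_hat], create_graph=True)
    if not np.isfinite(g.data).all():
        raise FloatingPointError(
            "non-finite critic gradients at interpolates "
            f"(|grad| max = {np.abs(g.data).max()})")
    sq = (g * g).reshape((B, -1)).sum(axis=1)
    # floor keeps the sqrt backward finite when a gradient vanishes exactly
    norms = nn.sqrt(nn.maximum_const(sq, 1e-24))
    dev = norms - 1.0
    return float(lambda_gp) * (dev * dev).mean()


def critic_loss(critic, x_real, x_fake, cfg: GanLossConfig = GanLossConfig(),
                rng=None, eps_values=None) -> Tensor:
    """Wasserstein critic loss, optionally with the gradient penalty."""
    loss = (-critic(nn.as_tensor(x_real))).mean() + critic(nn.as_tensor(x_fake)).mean()
    if cfg.use_penalty:
        loss = loss + gradient_penalty(critic, x_real, x_fake, cfg.lambda_gp,
                                       rng=rng, eps_values=eps_values)
    return loss


def generator_loss(z: Tensor, generator, critic) -> Tensor:
    return (-critic(generator(nn.as_tensor(z)))).mean()


# ---------------------------------------------------------------------------
# sampling / checkpoints
# ---------------------------------------------------------------------------

def sample_images(generator: Generator, n: int, seed: int = 0,
                  batch_size: int = 32) -> np.ndarray:
    """Draw ``n`` images in [0,1] (tanh output remapped by ``(x+1)/2``)."""
    rng = np.random.default_rng(seed)
    generator.eval()
    out = []
    with nn.no_grad():
        for start in range(0, n, batch_size):
            b = min(batch_size, n - start)
            z = Tensor(rng.standard_normal((b, generator.cfg.latent_dim)).astype(np.float32))
            imgs = generator(z).data
            out.append((imgs + 1.0) / 2.0)
    generator.train()
    if not out:
        return np.empty((0, 3, generator.cfg.image_size, generator.cfg.image_size),
                        dtype=np.float32)
    return np.clip(np.concatenate(out), 0.0, 1.0)


def save_checkpoint(record: CheckpointRecord, path) -> None:
    path = pathlib.Path(path)
    np.savez(path.with_suffix(".npz"), **record.state)
    meta = {"epoch": record.epoch, "fid": record.fid_score}
    path.with_suffix(".json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_rgsgan(images: np.ndarray,
                 gen_cfg: GeneratorConfig,
                 disc_cfg: DiscriminatorConfig,
                 loss_cfg: GanLossConfig = GanLossConfig(),
                 train_cfg: GanTrainConfig = GanTrainConfig(),
                 fid_fn: Callable[[np.ndarray], float] | None = None):
    """Alternating WGAN-GP optimisation with min-FID checkpoint selection.

    Parameters
    ----------
    images : (N, H, W, 3) array in [0, 1]; mapped internally to [-1, 1].
    fid_fn : callable mapping a batch of generated [0,1] images (N,3,H,W)
        to a scalar FID against the training distribution.  When omitted,
        checkpoints are scored by epoch order (last saved wins ties).

    Returns
    -------
    (generator, best_record, log) where ``log`` is a list of per-step
    dicts with finite critic/generator losses.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_cfg.seed)
    gen = Generator(gen_cfg, rng=np.random.default_rng(rng.integers(2 ** 31)))
    disc = Discriminator(disc_cfg, rng=np.random.default_rng(rng.integers(2 ** 31)))
    opt_g = nn.Adam(gen.parameters(), lr=train_cfg.lr_generator, betas=train_cfg.betas)
    opt_d = nn.Adam(disc.parameters(), lr=train_cfg.lr_discriminator, betas=train_cfg.betas)

    data = np.ascontiguousarray(
        (images.transpose(0, 3, 1, 2).astype(np.float32) * 2.0) - 1.0)
    n = len(data)
    bs = min(train_cfg.batch_size, n)
    log: list[dict] = []
    checkpoints: list[CheckpointRecord] = []
    step = 0

    def checkpoint(epoch):
        fid = float("nan")
        if fid_fn is not None:
            fake = sample_images(gen, min(n, 64), seed=int(rng.integers(2 ** 31)))
            fid = float(fid_fn(fake))
        checkpoints.append(CheckpointRecord(epoch, fid, gen.state_dict()))
        log.append({"epoch": epoch, "checkpoint_fid": fid})

    if fid_fn is not None:
        fake0 = sample_images(gen, min(n, 64), seed=int(rng.integers(2 ** 31)))
        log.append({"epoch": 0, "initial_fid": float(fid_fn(fake0))})

    for epoch in range(train_cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = perm[start:start + bs]
            x_real = Tensor(data[idx])
            z = Tensor(rng.standard_normal((bs, gen_cfg.latent_dim)).astype(np.float32))
            with nn.no_grad():
                x_fake = Tensor(gen(z).data)
            d_loss = critic_loss(disc, x_real, x_fake, loss_cfg,
                                 eps_values=rng.uniform(0, 1, bs))
            if not np.isfinite(d_loss.data):
                raise FloatingPointError(f"critic loss diverged at epoch {epoch}")
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            entry = {"epoch": epoch, "step": step, "d_loss": float(d_loss.data)}
            step += 1
            if step % loss_cfg.n_critic == 0:
                z2 = Tensor(rng.standard_normal((bs, gen_cfg.latent_dim)).astype(np.float32))
                g_loss = generator_loss(z2, gen, disc)
                if not np.isfinite(g_loss.data):
                    raise FloatingPointError(f"generator loss diverged at epoch {epoch}")
                opt_g.zero_grad()
                g_loss.backward()
                opt_g.step()
                entry["g_loss"] = float(g_loss.data)
            log.append(entry)
        if (epoch + 1) % train_cfg.checkpoint_every == 0:
            checkpoint(epoch + 1)
    if not checkpoints:
        checkpoint(train_cfg.epochs)
    if fid_fn is not None:
        best = min(checkpoints, key=lambda r: r.fid_score)
    else:
        best = checkpoints[-1]
    gen.load_state_dict(best.state)
    return gen, best, log
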