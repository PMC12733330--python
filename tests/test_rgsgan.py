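"""Generator/critic contracts and the gradient-penalty loss oracles."""

import numpy as np
import pytest

import grainforge.nn as nn
from grainforge.nn import Tensor
from grainforge import rgsgan as R

from conftest import fd_grad


@pytest.fixture(scope="module")
def smoke_gen():
    cfg = R.smoke_generator_config(64)
    return R.Generator(cfg, rng=np.random.default_rng(0)), cfg


@pytest.fixture(scope="module")
def smoke_disc():
    cfg = R.smoke_discriminator_config(64)
    return R.Discriminator(cfg, rng=np.random.default_rng(1)), cfg


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def test_generator_output_shape_range_and_determinism(smoke_gen):
    gen, cfg = smoke_gen
    z = Tensor(np.random.default_rng(2).standard_normal((4, cfg.latent_dim)).astype(np.float32))
    with nn.no_grad():
        a = gen(z).data
        b = gen(z).data
    assert a.shape == (4, 3, 64, 64)
    assert np.abs(a).max() <= 1.0
    assert np.array_equal(a, b)


def test_generator_rejects_wrong_latent_dimension(smoke_gen):
    gen, _ = smoke_gen
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((2, 37), dtype=np.float32)))


def test_full_scale_generator_config_builds_the_224_ladder():
    cfg = R.GeneratorConfig()
    assert cfg.base_size * 2 ** (len(cfg.stage_channels) - 1) == 224
    assert cfg.stage_channels[-1] == 3


def test_gscsa_block_upsamples_and_matches_forced_gate_composition():
    rng = np.random.default_rng(3)
    block = R.GSCSABlock(8, 4, rng=np.random.default_rng(4), dtype=np.float64)
    x = Tensor(rng.normal(size=(2, 8, 8, 8)))
    out = block(x)
    assert out.shape == (2, 4, 16, 16)
    assert np.isfinite(out.data).all()

    # zero the SCSA convs: attention gates collapse to 0.25 * 0.5 = 0.125,
    # so the block must equal ReLU(BN(ConvT(1.125 x)))
    for p in block.scsa.parameters():
        if p.data.ndim >= 3:
            p.data = np.zeros_like(p.data)
    got = block(x)
    expect = block.act(block.bn(block.up(x * 1.125)))
    assert np.allclose(got.data, expect.data, atol=1e-10)


# ---------------------------------------------------------------------------
# critic
# ---------------------------------------------------------------------------

def test_discriminator_scores_shape_and_structure(smoke_disc):
    disc, _ = smoke_disc
    x = Tensor(np.random.default_rng(5).uniform(-1, 1, (3, 3, 64, 64)).astype(np.float32))
    scores = disc(x)
    assert scores.shape == (3,)
    assert disc.n_downsampling_convs() == 6
    assert not any(isinstance(m, nn.Linear) for m in disc.modules())


def test_discriminator_scores_are_unbounded():
    """No squashing: scaling the scoring head scales the scores past 1."""
    disc = R.Discriminator(R.smoke_discriminator_config(64),
                           rng=np.random.default_rng(6))
    x = Tensor(np.ones((1, 3, 64, 64), dtype=np.float32))
    s0 = float(disc(x).data[0])
    disc.score.weight.data *= 1000.0
    disc.score.bias.data = disc.score.bias.data + 5.0
    s1 = float(disc(x).data[0])
    assert abs(s1) > 1.0
    assert s1 != pytest.approx(s0)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class _LinearCritic:
    """D(x) = <w, x> with configurable norm."""

    def __init__(self, shape, norm=1.0, seed=0):
        w = np.random.default_rng(seed).normal(size=shape)
        self.w = Tensor(norm * w / np.linalg.norm(w))

    def __call__(self, x):
        return (x * self.w).sum(axis=(1, 2, 3))


class _ConstantCritic:
    def __init__(self, c):
        self.c = c

    def __call__(self, x):
        return x.sum(axis=(1, 2, 3)) * 0.0 + self.c


def _batch(rng, b=4, size=8):
    xr = Tensor(rng.uniform(-1, 1, (b, 3, size, size)))
    xf = Tensor(rng.uniform(-1, 1, (b, 3, size, size)))
    return xr, xf


def test_gradient_penalty_zero_for_unit_norm_linear_critic(rng):
    xr, xf = _batch(rng)
    critic = _LinearCritic((3, 8, 8), norm=1.0)
    gp = R.gradient_penalty(critic, xr, xf, lambda_gp=10.0, rng=np.random.default_rng(1))
    assert float(gp.data) == pytest.approx(0.0, abs=1e-9)


def test_gradient_penalty_equals_lambda_for_constant_critic(rng):
    xr, xf = _batch(rng)
    gp = R.gradient_penalty(_ConstantCritic(3.0), xr, xf, lambda_gp=7.5,
                            rng=np.random.default_rng(2))
    assert float(gp.data) == pytest.approx(7.5, rel=1e-9)


def test_gradient_penalty_nonnegative_for_real_critic(rng):
    xr, xf = _batch(rng)
    disc = R.Discriminator(R.smoke_discriminator_config(64),
                           rng=np.random.default_rng(7))
    xr64 = Tensor(rng.uniform(-1, 1, (2, 3, 64, 64)).astype(np.float32))
    xf64 = Tensor(rng.uniform(-1, 1, (2, 3, 64, 64)).astype(np.float32))
    gp = R.gradient_penalty(disc, xr64, xf64, lambda_gp=10.0,
                            rng=np.random.default_rng(3))
    assert float(gp.data) >= 0.0


def test_gradient_penalty_quadratic_critic_matches_finite_differences(rng):
    """D(x) = ||x||^2 / 2: compare the penalty against a finite-difference
    evaluation of the same expression at fixed interpolates."""
    b = 3
    xr = rng.uniform(-1, 1, (b, 3, 4, 4))
    xf = rng.uniform(-1, 1, (b, 3, 4, 4))
    eps = np.random.default_rng(4).uniform(0, 1, b)
    lam = 10.0

    def quad(x):
        return (x * x).sum(axis=(1, 2, 3)) * 0.5

    gp = R.gradient_penalty(quad, Tensor(xr), Tensor(xf), lam, eps_values=eps)

    xhat = eps.reshape(-1, 1, 1, 1) * xr + (1 - eps.reshape(-1, 1, 1, 1)) * xf
    norms = np.empty(b)
    for i in range(b):
        g = fd_grad(lambda xd: float((xd ** 2).sum() * 0.5), xhat[i], eps=1e-5)
        norms[i] = np.linalg.norm(g)
    expect = lam * np.mean((norms - 1.0) ** 2)
    assert float(gp.data) == pytest.approx(expect, rel=1e-3)


def test_critic_loss_constant_cancellation_and_penalty_consistency(rng):
    xr, xf = _batch(rng)
    cst = _ConstantCritic(4.2)
    with_pen = R.critic_loss(cst, xr, xf, R.GanLossConfig(lambda_gp=10.0),
                             eps_values=np.full(4, 0.5))
    without = R.critic_loss(cst, xr, xf, R.GanLossConfig(use_penalty=False))
    assert float(with_pen.data) == pytest.approx(10.0, rel=1e-9)
    assert float(without.data) == pytest.approx(0.0, abs=1e-9)

    critic = _LinearCritic((3, 8, 8), norm=2.5, seed=3)
    eps = rng.uniform(0, 1, 4)
    full = R.critic_loss(critic, xr, xf, R.GanLossConfig(), eps_values=eps)
    plain = R.critic_loss(critic, xr, xf, R.GanLossConfig(use_penalty=False))
    pen = R.gradient_penalty(critic, xr, xf, 10.0, eps_values=eps)
    assert float(full.data) - float(plain.data) == pytest.approx(float(pen.data), rel=1e-9)


def test_generator_loss_constant_critic_and_recomposition(smoke_gen, smoke_disc):
    gen, gcfg = smoke_gen
    disc, _ = smoke_disc
    z = Tensor(np.random.default_rng(8).standard_normal((2, gcfg.latent_dim)).astype(np.float32))
    assert float(R.generator_loss(z, gen, _ConstantCritic(2.0)).data) == pytest.approx(-2.0, rel=1e-6)
    assert float(R.generator_loss(z, gen, _ConstantCritic(0.0)).data) == pytest.approx(0.0, abs=1e-7)
    manual = -float(disc(gen(z)).data.mean())
    assert float(R.generator_loss(z, gen, disc).data) == pytest.approx(manual, rel=1e-5)


# ---------------------------------------------------------------------------
# sampling + training loop contracts
# ---------------------------------------------------------------------------

def test_sample_images_range_determinism_and_empty(smoke_gen):
    gen, _ = smoke_gen
    imgs = R.sample_images(gen, 10, seed=3)
    assert imgs.shape == (10, 3, 64, 64)
    assert imgs.min() >= 0.0 and imgs.max() <= 1.0
    assert np.array_equal(imgs, R.sample_images(gen, 10, seed=3))
    assert R.sample_images(gen, 0, seed=0).shape == (0, 3, 64, 64)


def test_training_is_seed_deterministic_and_selects_min_fid():
    from grainforge.image_data import make_synthetic_kernel_set
    from grainforge import metrics as mt
    ds = make_synthetic_kernel_set(4, seed=0, image_size=32)
    stats_real = mt.feature_stats(ds.images.transpose(0, 3, 1, 2))
    fid_fn = lambda fake: mt.fid(stats_real, mt.feature_stats(fake))
    kw = dict(gen_cfg=R.smoke_generator_config(32),
              disc_cfg=R.smoke_discriminator_config(32),
              loss_cfg=R.GanLossConfig(),
              train_cfg=R.GanTrainConfig(epochs=2, batch_size=8,
                                         checkpoint_every=1, seed=5),
              fid_fn=fid_fn)
    gen1, best1, log1 = R.train_rgsgan(ds.images, **kw)
    gen2, best2, log2 = R.train_rgsgan(ds.images, **kw)
    steps1 = [e["d_loss"] for e in log1 if "d_loss" in e]
    steps2 = [e["d_loss"] for e in log2 if "d_loss" in e]
    assert steps1 == steps2
    assert all(np.isfinite(v) for v in steps1)
    assert best1.epoch == best2.epoch and best1.fid_score == best2.fid_score
    ckpt_fids = [e["checkpoint_fid"] for e in log1 if "checkpoint_fid" in e]
    assert len(ckpt_fids) == 2  # one per epoch at checkpoint_every=1
    assert best1.fid_score == min(ckpt_fids)
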