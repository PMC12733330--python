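"""MACR blocks, network shapes, param/MAC accounting, calibration, ablation."""

import dataclasses

import numpy as np
import pytest

import grainforge.nn as nn
from grainforge.nn import Tensor
from grainforge import macrnet as M


@pytest.fixture(scope="module")
def ref_cfg():
    return M.load_frozen_config()


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def test_block1_and_block2_shape_contracts(rng):
    b1 = M.MACRBlock(64, 64, stride=1, rng=np.random.default_rng(0))
    b2 = M.MACRBlock(64, 128, stride=2, rng=np.random.default_rng(1))
    x = Tensor(rng.normal(size=(2, 64, 56, 56)).astype(np.float32))
    with nn.no_grad():
        assert b1(x).shape == (2, 64, 56, 56)
        assert b2(x).shape == (2, 128, 28, 28)
    assert b1.block_type == "maintaining"
    assert b2.block_type == "downsampling"
    assert M.MACRBlock(64, 128, stride=1).block_type == "convolutional"


def test_block1_zeroed_main_path_is_exact_identity(rng):
    block = M.MACRBlock(16, 16, stride=1, rng=np.random.default_rng(2),
                        dtype=np.float64)
    for p in block.parameters():
        if p.data.ndim >= 3:
            p.data = np.zeros_like(p.data)
    block.bn.gamma.data = np.zeros_like(block.bn.gamma.data)
    x = Tensor(rng.normal(size=(2, 16, 8, 8)))
    out = block(x)
    assert np.array_equal(out.data, x.data)


def test_branch_widths_sum_to_output_channels():
    for c in (64, 128, 255, 1024):
        w = M.branch_widths(c)
        assert sum(w.values()) == c
        w3 = M.branch_widths(c, (1, 5, 7, 9))
        assert sum(w3.values()) == c and 3 not in w3


def test_asymmetric_pair_has_full_kxk_receptive_field():
    """Impulse response of the kx1 o 1xk pair spans a k x k square."""
    for k in (3, 5, 7, 9):
        v = nn.Conv2d(1, 1, (k, 1), padding=(k // 2, 0), bias=False)
        h = nn.Conv2d(1, 1, (1, k), padding=(0, k // 2), bias=False)
        v.weight.data = np.ones_like(v.weight.data)
        h.weight.data = np.ones_like(h.weight.data)
        impulse = np.zeros((1, 1, 19, 19), dtype=np.float32)
        impulse[0, 0, 9, 9] = 1.0
        with nn.no_grad():
            resp = h(v(Tensor(impulse))).data[0, 0]
        ys, xs = np.nonzero(resp)
        assert ys.max() - ys.min() + 1 == k
        assert xs.max() - xs.min() + 1 == k


# ---------------------------------------------------------------------------
# whole network
# ---------------------------------------------------------------------------

def test_network_shapes_on_smoke_config(rng):
    model = M.build_macrnet(M.smoke_config(), seed=0)
    x = Tensor(rng.normal(size=(2, 3, 32, 32)).astype(np.float32))
    with nn.no_grad():
        stem = model.stem(x)
        logits = model(x)
    assert stem.shape == (2, 16, 16, 16)
    assert logits.shape == (2, 6)
    assert np.isfinite(logits.data).all()


def test_reference_network_stem_and_head_dimensions(ref_cfg):
    model = M.build_macrnet(ref_cfg, seed=0)
    x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 224, 224)).astype(np.float32))
    with nn.no_grad():
        stem = model.stem(x)
        feats = model.features(x)
        logits = model(x)
    assert stem.shape == (1, 64, 112, 112)
    assert feats.shape == (1, 1024)
    assert logits.shape == (1, 6)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_param_count_closed_forms():
    lin = nn.Linear(1024, 6)
    assert lin.param_count() == 1024 * 6 + 6
    conv = nn.Conv2d(3, 64, 7, bias=False)
    assert conv.param_count() == 7 * 7 * 3 * 64


def test_param_count_matches_per_layer_enumeration_on_toy_config():
    cfg = M.MACRNetConfig(image_size=32, stem_channels=8,
                          stage_channels=(16, 32), stage_depths=(1, 1),
                          width_multiplier=1.0, n_classes=4)
    model = M.build_macrnet(cfg)
    # independent enumeration: walk every parameter tensor
    by_hand = sum(int(np.prod(p.data.shape)) for _, p in model.named_parameters())
    assert M.count_params(model) == by_hand == M.config_param_count(cfg)


def test_mac_count_matches_bruteforce_sliding_window():
    """One conv layer on an 8x8 input, counted by literally sliding the kernel."""
    conv = nn.Conv2d(2, 3, 3, stride=1, padding=1, bias=False)
    macs = conv._walk_macs((2, 8, 8))[0]
    count = 0
    for _ in range(3):            # output channels
        for oy in range(8):
            for ox in range(8):
                count += 3 * 3 * 2  # kernel taps x input channels
    assert macs == count


def test_stem_mac_closed_form():
    conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
    assert conv._walk_macs((3, 224, 224))[0] == 49 * 3 * 64 * 112 * 112 == 118013952


def test_model_and_config_counts_agree(ref_cfg):
    model = M.build_macrnet(ref_cfg, seed=0)
    assert M.count_params(model) == M.config_param_count(ref_cfg)
    assert M.count_macs(model, 224) == M.config_mac_count(ref_cfg)


def test_resnet18_mac_scale():
    macs = M.count_macs(M.build_resnet18(), 224)
    assert abs(macs / 1e9 - 1.826) / 1.826 < 0.01


# ---------------------------------------------------------------------------
# calibration / ablation
# ---------------------------------------------------------------------------

def test_calibration_is_deterministic_and_reports_infeasible_targets():
    res = M.calibrate_config(1e3, 1e6, tolerance=0.01)
    assert not res.ok
    a = M.calibrate_config(depth_range=range(1, 3), multiplier_step=0.01)
    b = M.calibrate_config(depth_range=range(1, 3), multiplier_step=0.01)
    assert a.config == b.config


def test_calibration_rejects_bad_tolerance():
    with pytest.raises(M.ConfigurationError):
        M.calibrate_config(tolerance=0.5)
    with pytest.raises(M.ConfigurationError):
        M.calibrate_config(target_params=-1)


def test_remove_branch_variants_build_and_stay_near_reference_budget(ref_cfg):
    ref_params = M.config_param_count(ref_cfg)
    for k in (3, 5, 7, 9):
        variant = M.remove_branch(ref_cfg, k)
        assert k not in variant.branch_kernels
        delta = abs(M.config_param_count(variant) - ref_params) / ref_params
        assert delta < 0.02
    with pytest.raises(M.ConfigurationError):
        M.remove_branch(ref_cfg, 1)


def test_removed_branch_absent_from_built_blocks(ref_cfg):
    variant = M.remove_branch(dataclasses.replace(
        M.smoke_config()), 7)
    model = M.build_macrnet(variant)
    for m in model.modules():
        if isinstance(m, M.MACRBlock):
            assert 7 not in m.kernels
            assert not hasattr(m, "branch7")
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 32, 32)).astype(np.float32))
    with nn.no_grad():
        assert model(x).shape == (1, 6)


def test_branch_removal_strictly_decreases_main_path_macs():
    """Before redistribution, every asymmetric branch does strictly
    positive convolution work, so deleting it lowers the block's MACs."""
    block = M.MACRBlock(32, 32, stride=1)
    in_shape = (32, 16, 16)
    branch_macs = {k: getattr(block, f"branch{k}")._walk_macs(in_shape)[0]
                   for k in block.kernels}
    total = sum(branch_macs.values())
    for k in (3, 5, 7, 9):
        assert branch_macs[k] > 0
        assert total - branch_macs[k] < total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_classifier_training_is_deterministic_and_tracks_best_val(small_kernel_set):
    x = M.to_model_input(small_kernel_set.images)
    y = small_kernel_set.labels
    cfg = M.ClassifierTrainConfig(epochs=3, seed=9)

    def run():
        model = M.build_macrnet(M.smoke_config(), seed=4)
        return M.train_classifier(model, x, y, cfg, val_images=x, val_labels=y)

    m1, log1 = run()
    m2, log2 = run()
    for (k1, p1), (k2, p2) in zip(sorted(m1.state_dict().items()),
                                  sorted(m2.state_dict().items())):
        assert k1 == k2 and np.array_equal(p1, p2)
    assert [e["val_acc"] for e in log1] == [e["val_acc"] for e in log2]
    best_val = max(e["val_acc"] for e in log1)
    acc, _ = M.evaluate_classifier(m1, x, y)
    assert acc == pytest.approx(best_val, abs=1e-9)
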