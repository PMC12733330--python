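"""Metric oracles: IS, FID, macro PRF, run statistics, k-fold summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grainforge import metrics as mt


# ---------------------------------------------------------------------------
# Inception Score
# ---------------------------------------------------------------------------

def test_is_uniform_rows_give_one():
    table = mt.ClassProbabilityTable(np.full((30, 6), 1 / 6))
    mean, std = mt.inception_score(table, n_splits=3)
    assert mean == pytest.approx(1.0, abs=1e-12)
    assert std == pytest.approx(0.0, abs=1e-12)


def test_is_balanced_one_hot_gives_class_count():
    rows = np.eye(6)[np.arange(60) % 6]
    mean, _ = mt.inception_score(mt.ClassProbabilityTable(rows), n_splits=1)
    assert mean == pytest.approx(6.0, rel=1e-12)


def test_is_matches_bruteforce_on_random_table(rng):
    raw = rng.uniform(0.01, 1.0, (50, 6))
    rows = raw / raw.sum(axis=1, keepdims=True)
    mean, std = mt.inception_score(mt.ClassProbabilityTable(rows), n_splits=5)

    # element-by-element brute force
    scores = []
    for part in np.array_split(rows, 5):
        marg = part.mean(axis=0)
        kls = []
        for r in part:
            kl = 0.0
            for y in range(6):
                if r[y] > 0:
                    kl += r[y] * np.log(r[y] / marg[y])
            kls.append(kl)
        scores.append(np.exp(np.mean(kls)))
    assert mean == pytest.approx(np.mean(scores), abs=1e-8)
    assert std == pytest.approx(np.std(scores), abs=1e-8)


def test_is_rejects_unnormalised_rows_and_bounds_hold(rng):
    with pytest.raises(mt.ValidationError):
        mt.ClassProbabilityTable(np.full((10, 6), 0.5))
    raw = rng.uniform(0.01, 1.0, (40, 6))
    rows = raw / raw.sum(axis=1, keepdims=True)
    mean, _ = mt.inception_score(mt.ClassProbabilityTable(rows), n_splits=4)
    assert 1.0 - 1e-9 <= mean <= 6.0 + 1e-9


# ---------------------------------------------------------------------------
# feature stats + FID
# ---------------------------------------------------------------------------

def test_feature_stats_identical_images_zero_covariance():
    imgs = np.ones((5, 3, 8, 8)) * 0.4
    stats = mt.feature_stats(imgs)
    assert np.allclose(stats.sigma, 0.0)
    assert stats.n == 5


def test_toy_embedder_hand_computed_on_constant_images():
    imgs = np.zeros((2, 3, 8, 8))
    imgs[0, 0], imgs[0, 1], imgs[0, 2] = 0.2, 0.4, 0.6
    imgs[1] = 0.5
    f = mt.toy_embedder(imgs)
    assert np.allclose(f[0, :3], [0.2, 0.4, 0.6])
    assert np.allclose(f[0, 3:6], 0.0)          # constant channels: zero std
    assert f[0, 6] == pytest.approx((0.2 + 0.4 + 0.6) / 3)
    assert np.allclose(f[1, :3], 0.5)


def test_feature_stats_invariant_under_permutation(rng):
    imgs = rng.uniform(0, 1, (8, 3, 16, 16))
    a = mt.feature_stats(imgs)
    b = mt.feature_stats(imgs[rng.permutation(8)])
    assert np.allclose(a.mu, b.mu) and np.allclose(a.sigma, b.sigma)
    with pytest.raises(mt.ValidationError):
        mt.feature_stats(imgs[:1])


def test_fid_closed_form_gaussian_cases():
    s = mt.FeatureStats(np.zeros(3), np.eye(3), 10)
    assert mt.fid(s, s) == pytest.approx(0.0, abs=1e-12)
    a = mt.FeatureStats(np.array([0.0]), np.array([[1.0]]), 10)
    b = mt.FeatureStats(np.array([1.0]), np.array([[1.0]]), 10)
    assert mt.fid(a, b) == pytest.approx(1.0, rel=1e-12)
    c = mt.FeatureStats(np.zeros(2), np.eye(2), 10)
    d = mt.FeatureStats(np.zeros(2), 4 * np.eye(2), 10)
    assert mt.fid(c, d) == pytest.approx(2.0, rel=1e-12)


def test_fid_symmetry_and_diagonal_closed_form(rng):
    for _ in range(5):
        mr, mg = rng.normal(size=4), rng.normal(size=4)
        vr, vg = rng.uniform(0.5, 2, 4), rng.uniform(0.5, 2, 4)
        a = mt.FeatureStats(mr, np.diag(vr), 9)
        b = mt.FeatureStats(mg, np.diag(vg), 9)
        f = mt.fid(a, b)
        assert f == pytest.approx(mt.fid(b, a), abs=1e-8)
        closed = ((mr - mg) ** 2).sum() + ((np.sqrt(vr) - np.sqrt(vg)) ** 2).sum()
        assert f == pytest.approx(closed, abs=1e-8)
        assert f >= 0.0


def test_fid_matched_count_protocol(rng):
    real = rng.uniform(0, 1, (10, 3, 8, 8))
    fake = rng.uniform(0, 1, (6, 3, 8, 8))
    with pytest.raises(mt.ValidationError, match="matched"):
        mt.fid_between(real, fake)
    # explicit override allows the comparison
    assert mt.fid_between(real, fake, require_matched_counts=False) >= 0.0


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def test_perfect_predictions_score_one():
    y = np.repeat(np.arange(6), 10)
    cm, per_class, macro = mt.confusion_and_macro(y, y, 6)
    assert np.array_equal(cm, np.diag([10] * 6))
    assert macro["accuracy"] == 1.0
    assert macro["precision"] == macro["recall"] == macro["f1"] == 1.0


def test_single_class_prf_forced_arithmetic():
    """TP=50, FP=10, FN=5 for class 0 -> P .8333, R .9091, F1 .8696."""
    y_true = np.array([0] * 55 + [1] * 10 + [1] * 35)
    y_pred = np.array([0] * 50 + [1] * 5 + [0] * 10 + [1] * 35)
    _, per_class, _ = mt.confusion_and_macro(y_true, y_pred, 2)
    assert per_class[0]["precision"] == pytest.approx(0.8333, abs=5e-5)
    assert per_class[0]["recall"] == pytest.approx(0.9091, abs=5e-5)
    assert per_class[0]["f1"] == pytest.approx(0.8696, abs=5e-5)


def test_macro_metrics_match_independent_hand_computation(rng):
    y_true = rng.integers(0, 6, 300)
    y_pred = rng.integers(0, 6, 300)
    cm, per_class, macro = mt.confusion_and_macro(y_true, y_pred, 6)
    # independent per-class loop
    precs, recs, f1s = [], [], []
    for c in range(6):
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p); recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    assert macro["precision"] == pytest.approx(np.mean(precs), abs=1e-12)
    assert macro["recall"] == pytest.approx(np.mean(recs), abs=1e-12)
    assert macro["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)
    assert macro["accuracy"] == pytest.approx((y_true == y_pred).mean(), abs=1e-12)
    assert macro["f1"] <= max(pc["f1"] for pc in per_class) + 1e-12


def test_accuracy_invariant_under_label_permutation(rng):
    y_true = rng.integers(0, 6, 200)
    y_pred = rng.integers(0, 6, 200)
    perm = rng.permutation(6)
    _, _, m1 = mt.confusion_and_macro(y_true, y_pred, 6)
    _, _, m2 = mt.confusion_and_macro(perm[y_true], perm[y_pred], 6)
    assert m1["accuracy"] == pytest.approx(m2["accuracy"], abs=1e-12)


def test_degenerate_class_flags_zero_denominators():
    y_true = np.array([0, 0, 1, 1])
    y_pred = np.array([0, 0, 0, 0])  # class 1 never predicted
    _, per_class, macro = mt.confusion_and_macro(y_true, y_pred, 2)
    assert per_class[1]["precision"] == 0.0
    assert macro["degenerate"]


# ---------------------------------------------------------------------------
# run statistics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean,std,stderr,lo,hi", [
    (97.293, 0.045, 0.026, 97.18, 97.41),
    (94.882, 0.076, 0.044, 94.69, 95.07),
])
def test_three_run_t_intervals_reproduce_report_rows(mean, std, stderr, lo, hi):
    rep = mt.run_stats(mean, std, 3, 4.303)
    assert rep.stderr == pytest.approx(stderr, abs=1e-12)
    assert rep.ci_low == pytest.approx(lo, abs=1e-12)
    assert rep.ci_high == pytest.approx(hi, abs=1e-12)


def test_run_stats_degenerate_and_invalid_inputs():
    rep = mt.run_stats(98.8, 0.0, 3)
    assert rep.ci_low == rep.ci_high == pytest.approx(98.8)
    with pytest.raises(mt.ValidationError):
        mt.run_stats(98.8, 0.1, 1)
    with pytest.raises(mt.ValidationError):
        mt.run_stats(98.8, -0.1, 3)


@pytest.mark.parametrize("a,b,expect", [
    (98.813, 92.654, 6.16),
    (98.813, 95.801, 3.01),
    (50.0, 50.0, 0.0),
])
def test_improvement_deltas_round_half_up(a, b, expect):
    assert mt.improvement_delta(a, b, 2) == pytest.approx(expect, abs=1e-12)


@given(st.lists(st.floats(90, 100), min_size=2, max_size=8))
def test_kfold_summary_matches_direct_formulas(folds):
    mean, std, stderr = mt.kfold_summary(folds)
    arr = np.asarray(folds)
    assert mean == pytest.approx(arr.mean(), abs=1e-9)
    assert std == pytest.approx(arr.std(ddof=1), abs=1e-9)
    assert stderr == pytest.approx(std / np.sqrt(len(folds)), abs=1e-9)


def test_kfold_identical_folds_zero_spread():
    mean, std, stderr = mt.kfold_summary([98.8] * 5)
    assert mean == pytest.approx(98.8) and std == 0.0 and stderr == 0.0
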