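"""Generation- and classification-quality metrics.

* Inception Score: ``exp(E_x[ KL(p(y|x) || p(y)) ])`` over split groups.
* Frechet distance between Gaussian fits of embedded image features:
  ``||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2})`` with a pluggable
  embedder (a deterministic low-dimensional toy embedder for offline use;
  any 2048-d reference embedder plugs into the same interface).
* Confusion-matrix accuracy and macro precision/recall/F1.
* Multi-run t-interval statistics and k-fold summaries, carried in decimal
  arithmetic at the precision the report tables print.
"""

from __future__ import annotations

import dataclasses
import decimal
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import linalg as sla
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ClassProbabilityTable", "FeatureStats", "EmbedderSpec", "RunStatsReport",
    "inception_score", "toy_embedder", "feature_stats", "fid",
    "confusion_and_macro", "run_stats", "improvement_delta", "kfold_summary",
]


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Inception Score
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassProbabilityTable:
    """Per-image conditional class distributions p(y|x), rows sum to 1."""

    rows: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 2:
            raise ValidationError("probability table must be 2-D")
        if (self.rows < 0).any():
            raise ValidationError("probabilities must be nonnegative")
        if not np.allclose(self.rows.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("every row must sum to 1 (within 1e-6)")

    @property
    def marginal(self) -> np.ndarray:
        return self.rows.mean(axis=0)


def inception_score(table: ClassProbabilityTable, n_splits: int = 10):
    """(mean, std) of ``exp(mean_x KL(p(y|x) || p(y)))`` over row splits.

    Natural log; ``0 * log 0 == 0``.  The marginal is recomputed inside
    every split, following the standard split-evaluation protocol.
    """
    rows = table.rows
    if len(rows) < n_splits:
        raise ValidationError(f"need at least {n_splits} rows for {n_splits} splits")
    scores = []
    for part in np.array_split(rows, n_splits):
        marginal = part.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(part > 0, np.log(part / marginal), 0.0)
        kl = (part * logs).sum(axis=1)
        scores.append(np.exp(kl.mean()))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std())


# ---------------------------------------------------------------------------
# embedders / FID
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EmbedderSpec:
    name: str
    feature_dim: int
    input_size: int = 224


def toy_embedder(images: np.ndarray) -> np.ndarray:
    """Deterministic 8-d embedding: channel means + grayscale moments.

    ``images`` is (N, 3, H, W) in [0, 1].  Features: 3 channel means,
    3 channel stds, grayscale mean and std of a 4x4-downsampled map.
    Cheap, training-free, and sensitive to exactly the colour/texture
    statistics the synthetic kernel classes differ in.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValidationError(f"expected (N,3,H,W), got {images.shape}")
    n, _, h, w = images.shape
    ch_mean = images.mean(axis=(2, 3))
    ch_std = images.std(axis=(2, 3))
    gray = images.mean(axis=1)
    fh, fw = max(h // 4, 1), max(w // 4, 1)
    gray = gray[:, :4 * fh, :4 * fw].reshape(n, 4, fh, 4, fw).mean(axis=(2, 4))
    return np.concatenate([ch_mean, ch_std,
                           gray.mean(axis=(1, 2))[:, None],
                           gray.std(axis=(1, 2))[:, None]], axis=1)


TOY_EMBEDDER_SPEC = EmbedderSpec("toy", feature_dim=8)


@dataclasses.dataclass
class FeatureStats:
    """Gaussian sufficient statistics (mean, covariance) of embedded images."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValidationError("covariance shape inconsistent with mean")


def feature_stats(images: np.ndarray,
                  embedder: Callable[[np.ndarray], np.ndarray] = toy_embedder
                  ) -> FeatureStats:
    """Embed images and fit the Gaussian (unbiased covariance)."""
    if len(images) < 2:
        raise ValidationError("need at least 2 images for covariance")
    feats = np.asarray(embedder(images), dtype=np.float64)
    mu = feats.mean(axis=0)
    sigma = np.cov(feats, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    return FeatureStats(mu, sigma, len(images))


def fid(stats_r: FeatureStats, stats_g: FeatureStats,
        require_matched_counts: bool = False) -> float:
    """Frechet distance between two Gaussian feature fits.

    The matrix square root of ``S_r S_g`` uses the Schur method; an
    imaginary residue above 1e-6 (relative) is a numerical error, below
    it is discarded.  Values in (-1e-6, 0) clamp to 0 with a warning.
    """
    if stats_r.mu.shape != stats_g.mu.shape:
        raise ValidationError("feature dimensions differ")
    if require_matched_counts and stats_r.n != stats_g.n:
        raise ValidationError(
            f"sample counts differ ({stats_r.n} vs {stats_g.n}); FID comparisons "
            "require matched counts unless explicitly overridden")
    diff = stats_r.mu - stats_g.mu
    prod = stats_r.sigma @ stats_g.sigma
    covmean = sla.sqrtm(prod)
    if not np.isfinite(covmean).all():
        raise FloatingPointError("matrix square root did not converge")
    if np.iscomplexobj(covmean):
        resid = np.abs(covmean.imag).max()
        scale = max(np.abs(covmean.real).max(), 1.0)
        if resid / scale > 1e-6:
            raise FloatingPointError(
                f"matrix square root has imaginary residue {resid:g}")
        covmean = covmean.real
    value = float(diff @ diff + np.trace(stats_r.sigma + stats_g.sigma - 2.0 * covmean))
    if value < 0:
        if value > -1e-6:
            warnings.warn("FID clamped to 0 from a small negative value")
            value = 0.0
        else:
            raise FloatingPointError(f"FID came out negative: {value:g}")
    return value


def fid_between(images_real: np.ndarray, images_gen: np.ndarray,
                embedder=toy_embedder, require_matched_counts: bool = True) -> float:
    """FID of two image sets; enforces the matched-count protocol by default."""
    sr = feature_stats(images_real, embedder)
    sg = feature_stats(images_gen, embedder)
    return fid(sr, sg, require_matched_counts=require_matched_counts)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def confusion_and_macro(true_labels, predicted_labels, n_classes: int):
    """Confusion matrix (rows = true) plus per-class and macro P/R/F1.

    One-vs-rest per class; empty denominators yield 0 and set the
    ``degenerate`` flag.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValidationError("label arrays differ in length")
    cm = _sk_confusion(true_labels, predicted_labels, labels=np.arange(n_classes))
    per_class = []
    degenerate = False
    for c in range(n_classes):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if (tp + fp) == 0 or (tp + fn) == 0:
            degenerate = True
        per_class.append({"precision": prec, "recall": rec, "f1": f1})
    macro = {key: float(np.mean([pc[key] for pc in per_class]))
             for key in ("precision", "recall", "f1")}
    accuracy = float(np.trace(cm)) / cm.sum() if cm.sum() else 0.0
    macro["accuracy"] = accuracy
    macro["degenerate"] = degenerate
    return cm, per_class, macro


# ---------------------------------------------------------------------------
# run statistics
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(str(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class RunStatsReport:
    mean: float
    std: float
    n: int
    t_multiplier: float
    stderr: float       # std / sqrt(n), printed at 3 decimals
    ci_low: float       # mean -/+ t * stderr, printed at 2 decimals
    ci_high: float


def run_stats(mean: float, std: float, n: int = 3,
              t_multiplier: float = 4.303) -> RunStatsReport:
    """t-interval report from a printed (mean, std, n) row.

    The interval arithmetic is carried at the report table's printed
    precision: stderr is rounded (half-up) to 3 decimals, the half-width
    ``t * stderr`` to 3 decimals, and the bounds to 2 decimals.  With
    t = 4.303 (two-sided 95%, 2 degrees of freedom) this reproduces
    three-run report rows exactly.
    """
    if n < 2:
        raise ValidationError("need n >= 2 runs")
    if std < 0:
        raise ValidationError("std must be nonnegative")
    stderr = _round_half_up(std / np.sqrt(n), 3)
    half = _round_half_up(t_multiplier * stderr, 3)
    mean_d = decimal.Decimal(str(mean))
    half_d = decimal.Decimal(str(half))
    lo = _round_half_up(float(mean_d - half_d), 2)
    hi = _round_half_up(float(mean_d + half_d), 2)
    return RunStatsReport(mean, std, n, t_multiplier, stderr, lo, hi)


def improvement_delta(acc_a: float, acc_b: float, decimals: int = 2) -> float:
    """Half-up-rounded accuracy difference ``acc_a - acc_b``."""
    d = decimal.Decimal(str(acc_a)) - decimal.Decimal(str(acc_b))
    q = decimal.Decimal(10) ** -decimals
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


def kfold_summary(fold_accuracies: Sequence[float]):
    """(mean, sample std, stderr) across cross-validation folds."""
    accs = np.asarray(fold_accuracies, dtype=np.float64)
    if len(accs) < 2:
        raise ValidationError("need at least 2 folds")
    mean = float(accs.mean())
    std = float(accs.std(ddof=1))
    return mean, std, std / np.sqrt(len(accs))
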