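"""Image-set handling for corn-kernel defect recognition.

Covers loading directory-per-class image folders, per-channel
normalisation, stratified train/validation splitting, the conventional
(non-generative) augmentation pipeline, the synthetic kernel-image
generator used as a stand-in for real data in tests, and assembly of the
four augmentation dataset variants (original / generative /
non-generative / mixed).

Images are stored as float arrays in ``[0, 1]`` with shape ``H x W x 3``;
normalisation to model scale (classifier mean/std, or ``2x - 1`` for the
GAN) is applied lazily at model boundaries.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "DEFAULT_MEAN",
    "DEFAULT_STD",
    "LabeledImageSet",
    "NormalizationSpec",
    "SplitSpec",
    "DatasetVariant",
    "load_image_folder",
    "normalize_batch",
    "denormalize_batch",
    "split_train_val",
    "apply_nongen_augmentation",
    "make_synthetic_kernel_set",
    "assemble_variant",
    "save_image_folder",
]

#: AP = pest-attacked, BN = broken, FM = fusarium, HD = heat-damaged,
#: MY = moldy, NOR = normal.  Sorted order fixes label ids and the
#: confusion-matrix axes everywhere in the package.
DEFAULT_CLASS_NAMES = ("AP", "BN", "FM", "HD", "MY", "NOR")

#: Channel statistics of the corn-kernel imagery this pipeline targets.
DEFAULT_MEAN = (0.647, 0.638, 0.448)
DEFAULT_STD = (0.177, 0.192, 0.209)


class ConfigurationError(ValueError):
    """Raised for invalid pipeline configuration (bad paths, specs, tags)."""


@dataclasses.dataclass
class LabeledImageSet:
    """Labelled RGB images in [0,1], all the same spatial size."""

    images: np.ndarray  # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray  # (N,) int64 in {0..K-1}
    class_names: tuple = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ConfigurationError(
                f"{len(self.images)} images but {len(self.labels)} labels")
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ConfigurationError(f"labels outside 0..{k - 1}")

    def __len__(self):
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def per_class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx) -> "LabeledImageSet":
        return LabeledImageSet(self.images[idx], self.labels[idx], self.class_names)


@dataclasses.dataclass(frozen=True)
class NormalizationSpec:
    mean: tuple = DEFAULT_MEAN
    std: tuple = DEFAULT_STD

    def __post_init__(self):
        if len(self.mean) != 3 or len(self.std) != 3:
            raise ConfigurationError("mean/std must have 3 channels")
        if any(s <= 0 for s in self.std):
            raise ConfigurationError("std must be positive on every channel")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must lie in (0,1), got {self.train_fraction}")


_VARIANT_SOURCES = {
    "OD": {"real"},
    "GD": {"real", "generated"},
    "NGD": {"real", "transformed"},
    "MD": {"real", "generated", "transformed"},
}


@dataclasses.dataclass
class DatasetVariant:
    """One of the four augmentation regimes: OD, GD, NGD, MD."""

    tag: str
    data: LabeledImageSet
    per_class_counts: np.ndarray
    provenances: tuple


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def load_image_folder(root_path, class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
                      target_size: int = 224) -> LabeledImageSet:
    """Load a directory-per-class folder of PNG/JPEG images.

    Labels follow sorted class-name order; files are read in lexicographic
    order so repeated loads are byte-identical.
    """
    root = pathlib.Path(root_path)
    names = tuple(sorted(class_names))
    images, labels = [], []
    for label, name in enumerate(names):
        sub = root / name
        if not sub.is_dir():
            raise ConfigurationError(f"missing class directory: {sub}")
        files = sorted(p for p in sub.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise ConfigurationError(f"class directory is empty: {sub}")
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB")
                    if im.size != (target_size, target_size):
                        im = im.resize((target_size, target_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float32) / 255.0
            except (OSError, SyntaxError) as e:
                raise IOError(f"cannot decode image file {f}: {e}") from e
            images.append(arr)
            labels.append(label)
    return LabeledImageSet(np.stack(images), np.asarray(labels), names)


def save_image_folder(dataset: LabeledImageSet, root_path) -> None:
    """Write a set back out as one PNG folder per class."""
    root = pathlib.Path(root_path)
    counters = [0] * dataset.n_classes
    for img, label in zip(dataset.images, dataset.labels):
        sub = root / dataset.class_names[label]
        sub.mkdir(parents=True, exist_ok=True)
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(sub / f"{counters[label]:05d}.png")
        counters[label] += 1


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_batch(dataset: LabeledImageSet,
                    spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Per-channel ``(x - mean) / std``; returns (N, H, W, 3) float32."""
    mean = np.asarray(spec.mean, dtype=np.float32)
    std = np.asarray(spec.std, dtype=np.float32)
    return (dataset.images - mean) / std


def denormalize_batch(batch: np.ndarray,
                      spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    mean = np.asarray(spec.mean, dtype=np.float32)
    std = np.asarray(spec.std, dtype=np.float32)
    return batch * std + mean


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_train_val(dataset: LabeledImageSet, spec: SplitSpec):
    """Stratified, seeded, disjoint and exhaustive train/val partition."""
    counts = dataset.per_class_counts()
    if (counts < 2).any():
        raise ConfigurationError("every class needs at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx = [], []
    if spec.stratified:
        for c in range(dataset.n_classes):
            idx = np.nonzero(dataset.labels == c)[0]
            perm = rng.permutation(idx)
            n_train = int(round(spec.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_idx.append(perm[:n_train])
            val_idx.append(perm[n_train:])
        train_idx = np.sort(np.concatenate(train_idx))
        val_idx = np.sort(np.concatenate(val_idx))
    else:
        perm = rng.permutation(len(dataset))
        n_train = int(round(spec.train_fraction * len(dataset)))
        train_idx = np.sort(perm[:n_train])
        val_idx = np.sort(perm[n_train:])
    return dataset.subset(train_idx), dataset.subset(val_idx), train_idx, val_idx


def write_split_manifest(path, train_idx, val_idx) -> None:
    """Two-column manifest: sample index, split name."""
    with open(path, "w") as fh:
        for i in train_idx:
            fh.write(f"{int(i)}\ttrain\n")
        for i in val_idx:
            fh.write(f"{int(i)}\tval\n")


# ---------------------------------------------------------------------------
# non-generative augmentation
# ---------------------------------------------------------------------------

def apply_nongen_augmentation(dataset: LabeledImageSet, seed: int = 0,
                              scale_range=(0.6, 1.0), aspect_range=(3 / 4, 4 / 3),
                              flip_prob: float = 0.5) -> LabeledImageSet:
    """Seeded random-resized-crop followed by horizontal flip.

    The conventional augmentation pair for image classifiers: a random
    area/aspect crop resized back to the input size, then a coin-flip
    mirror.  Labels are preserved, output size is unchanged.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(dataset.images)
    n, H, W, _ = dataset.images.shape
    for i in range(n):
        img = dataset.images[i]
        crop = _random_resized_crop(img, rng, scale_range, aspect_range)
        if rng.random() < flip_prob:
            crop = crop[:, ::-1]
        out[i] = crop
    return LabeledImageSet(out, dataset.labels.copy(), dataset.class_names)


def _random_resized_crop(img: np.ndarray, rng, scale_range, aspect_range,
                         max_tries: int = 10) -> np.ndarray:
    H, W, _ = img.shape
    area = H * W
    for _ in range(max_tries):
        target_area = area * rng.uniform(*scale_range)
        log_ar = rng.uniform(np.log(aspect_range[0]), np.log(aspect_range[1]))
        ar = np.exp(log_ar)
        w = int(round(np.sqrt(target_area * ar)))
        h = int(round(np.sqrt(target_area / ar)))
        if 0 < w <= W and 0 < h <= H:
            top = int(rng.integers(0, H - h + 1))
            left = int(rng.integers(0, W - w + 1))
            patch = img[top:top + h, left:left + w]
            return _resize_bilinear(patch, H, W)
    return img.copy()  # degenerate fall-back: identity crop


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize without antialiasing (align-corners=False grid)."""
    h, w, _ = img.shape
    if (h, w) == (out_h, out_w):
        return img.copy()
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :, None]
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return (top * (1 - wy) + bot * wy).astype(img.dtype)


# ---------------------------------------------------------------------------
# synthetic kernel generator
# ---------------------------------------------------------------------------

# Base colours chosen so the pooled channel means land near the pipeline's
# default normalisation means while keeping the six classes visually
# separable.  Luminance ordering MY < NOR is forced by construction (dark
# mould spots subtract brightness from the same base ellipse).
_CLASS_BASE_COLOR = {
    "NOR": (0.86, 0.80, 0.42),   # smooth warm yellow
    "MY": (0.86, 0.80, 0.42),    # same base, darkened by mould spots
    "BN": (0.84, 0.78, 0.44),    # notched outline
    "AP": (0.84, 0.79, 0.43),    # small boreholes
    "HD": (0.72, 0.47, 0.30),    # global red-brown shift
    "FM": (0.90, 0.76, 0.66),    # pale pink-white streaks
}
_BACKGROUND = (0.56, 0.55, 0.36)


def make_synthetic_kernel_set(n_per_class: int, seed: int = 0,
                              image_size: int = 224,
                              class_names: Sequence[str] = DEFAULT_CLASS_NAMES
                              ) -> LabeledImageSet:
    """Procedural six-class kernel-image generator.

    Each image is an elliptical kernel on a dark background with a
    class-conditional defect signature: NOR smooth; MY dark green-gray
    spots; BN a polygonal notch removed; AP small dark boreholes; HD a
    global red-brown colour shift; FM pale pink-white streaks.  Ellipse
    axes, rotation, base colour and additive noise are jittered per image.
    Deterministic in (n_per_class, seed, image_size).
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    names = tuple(sorted(class_names))
    rng = np.random.default_rng(seed)
    size = image_size
    images, labels = [], []
    for label, name in enumerate(names):
        for _ in range(n_per_class):
            images.append(_draw_kernel(name, rng, size))
            labels.append(label)
    return LabeledImageSet(np.stack(images), np.asarray(labels), names)


def _draw_kernel(name: str, rng, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = size * rng.uniform(0.34, 0.42)   # semi-major
    b = size * rng.uniform(0.26, 0.32)   # semi-minor
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    base = np.asarray(_CLASS_BASE_COLOR[name], dtype=np.float32)
    base = base + rng.uniform(-0.04, 0.04, 3).astype(np.float32)
    bg = np.asarray(_BACKGROUND, dtype=np.float32)
    bg = bg + rng.uniform(-0.02, 0.02, 3).astype(np.float32)

    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = bg
    # gentle radial shading on the kernel body
    shade = 1.0 - 0.25 * np.sqrt(np.clip((u / a) ** 2 + (v / b) ** 2, 0, 1))
    body = base[None, None, :] * shade[:, :, None]
    img[ellipse] = body[ellipse]

    if name == "MY":
        n_spots = rng.integers(12, 20)
        spot = np.asarray((0.25, 0.30, 0.24), dtype=np.float32)  # dark green-gray
        for _ in range(n_spots):
            r = rng.uniform(0.02, 0.05) * size
            sy = cy + rng.uniform(-0.8, 0.8) * b
            sx = cx + rng.uniform(-0.8, 0.8) * a
            mask = ((xx - sx) ** 2 + (yy - sy) ** 2 <= r ** 2) & ellipse
            img[mask] = spot + rng.uniform(-0.03, 0.03, 3).astype(np.float32)
    elif name == "BN":
        # polygonal notch: remove a wedge from one end of the ellipse
        ang = rng.uniform(0, 2 * np.pi)
        nx, ny = np.cos(ang), np.sin(ang)
        cut = (u * nx + v * ny) > rng.uniform(0.35, 0.6) * a
        img[cut & ellipse] = bg
    elif name == "AP":
        n_holes = rng.integers(3, 6)
        hole = np.asarray((0.12, 0.10, 0.08), dtype=np.float32)
        for _ in range(n_holes):
            r = rng.uniform(0.015, 0.03) * size
            sy = cy + rng.uniform(-0.6, 0.6) * b
            sx = cx + rng.uniform(-0.6, 0.6) * a
            mask = ((xx - sx) ** 2 + (yy - sy) ** 2 <= r ** 2) & ellipse
            img[mask] = hole
    elif name == "FM":
        n_streaks = rng.integers(4, 8)
        streak = np.asarray((0.95, 0.88, 0.86), dtype=np.float32)  # pale pink-white
        for _ in range(n_streaks):
            ang = rng.uniform(0, np.pi)
            w = rng.uniform(0.01, 0.025) * size
            off = rng.uniform(-0.6, 0.6) * b
            d = np.abs((xx - cx) * np.sin(ang) - (yy - cy) * np.cos(ang) - off)
            mask = (d < w) & ellipse
            img[mask] = 0.5 * img[mask] + 0.5 * streak
    # HD and NOR need no local defects (HD is the global colour shift baked
    # into its base colour).

    img += rng.normal(0.0, 0.015, img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset variants
# ---------------------------------------------------------------------------

def assemble_variant(tag: str, real: LabeledImageSet,
                     generated: LabeledImageSet | None = None,
                     transformed: LabeledImageSet | None = None) -> DatasetVariant:
    """Concatenate sources according to the augmentation-variant contract.

    OD = real only, GD = real + generated, NGD = real + transformed,
    MD = real + generated + transformed.
    """
    if tag not in _VARIANT_SOURCES:
        raise ConfigurationError(f"unknown variant tag {tag!r}")
    allowed = _VARIANT_SOURCES[tag]
    parts, provs = [real], ["real"]
    for name, ds in (("generated", generated), ("transformed", transformed)):
        if ds is not None and len(ds):
            if name not in allowed:
                raise ConfigurationError(
                    f"variant {tag} does not accept {name} images")
            if ds.class_names != real.class_names:
                raise ConfigurationError("class names differ between sources")
            parts.append(ds)
            provs.append(name)
        elif name in allowed:
            raise ConfigurationError(f"variant {tag} requires {name} images")
    images = np.concatenate([p.images for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    data = LabeledImageSet(images, labels, real.class_names)
    return DatasetVariant(tag, data, data.per_class_counts(), tuple(provs))
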