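"""Dataset preparation: hold-out split, paired augmentation, resampling, 5-fold CV.

The order of operations mirrors the study design: the 90:10 hold-out split is
performed per source dataset *before* resampling, so no test sample is ever an
augmented copy of a training sample.  Resampling then equalizes the three crops'
contributions (default 1000 train / 100 test each): undersized datasets are
upsampled with paired geometric augmentation, the oversized one is randomly
sub-sampled without replacement.

Augmentations apply the identical geometric transform to image and mask; the
image is interpolated bilinearly with reflect padding while the mask is warped
as a class raster with nearest-neighbour interpolation and constant soil fill,
so augmented masks never contain off-palette colors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import AffineTransform, warp

from .palettes import SOIL, UNIFIED, classes_to_mask, mask_to_classes
from .synthetic import CROPS, DatasetBundle, SegSample

AUGMENTATION_OPS = ("rotation", "zoom", "shear", "hflip", "vflip",
                    "width_shift", "height_shift")

#: magnitude ranges for randomly drawn augmentations
MAGNITUDE_RANGES = {
    "rotation": (-25.0, 25.0),       # degrees
    "zoom": (0.8, 1.2),              # isotropic scale factor
    "shear": (-10.0, 10.0),          # degrees
    "hflip": (1.0, 1.0),
    "vflip": (1.0, 1.0),
    "width_shift": (-0.1, 0.1),      # fraction of width
    "height_shift": (-0.1, 0.1),     # fraction of height
}


@dataclass(frozen=True)
class AugmentationSpec:
    """One geometric operation with its magnitude."""

    op_name: str
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.op_name not in AUGMENTATION_OPS:
            raise ValueError(f"unknown op_name {self.op_name!r}; choose from {AUGMENTATION_OPS}")
        lo, hi = MAGNITUDE_RANGES[self.op_name]
        if not lo <= self.magnitude <= hi:
            raise ValueError(f"{self.op_name} magnitude {self.magnitude} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ResamplePlan:
    """Per-crop targets for the balanced design."""

    target_train: int = 1000
    target_test: int = 100
    direction: str = "auto"  # auto | upsample | downsample | none

    def __post_init__(self):
        if self.target_train < 0 or self.target_test < 0:
            raise ValueError("targets must be >= 0")
        if self.direction not in ("auto", "upsample", "downsample", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")


def holdout_split(bundle, train_ratio=0.9, seed=0):
    """Random per-crop 90:10 hold-out split (disjoint and exhaustive)."""
    if len(bundle) == 0:
        raise ValueError("cannot split an empty bundle")
    if not 0.0 < train_ratio < 1.0:
        raise ValueError("train_ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for crop in CROPS:
        idx = [i for i, s in enumerate(bundle.samples) if s.crop_id == crop]
        if not idx:
            continue
        perm = rng.permutation(len(idx))
        n_train = round(train_ratio * len(idx))
        train_idx.extend(idx[j] for j in perm[:n_train])
        test_idx.extend(idx[j] for j in perm[n_train:])
    return (bundle.subset(sorted(train_idx), "train"),
            bundle.subset(sorted(test_idx), "test"))


def _transform_for(spec, shape):
    h, w = shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    center = AffineTransform(translation=(-cx, -cy))
    uncenter = AffineTransform(translation=(cx, cy))
    op, m = spec.op_name, spec.magnitude
    if op == "rotation":
        core = AffineTransform(rotation=np.deg2rad(m))
    elif op == "zoom":
        core = AffineTransform(scale=(m, m))
    elif op == "shear":
        core = AffineTransform(shear=np.deg2rad(m))
    elif op == "hflip":
        core = AffineTransform(scale=(-1, 1))
    elif op == "vflip":
        core = AffineTransform(scale=(1, -1))
    elif op == "width_shift":
        return AffineTransform(translation=(m * w, 0))
    elif op == "height_shift":
        return AffineTransform(translation=(0, m * h))
    return center + core + uncenter


def augment_pair(sample, spec):
    """Apply one geometric op identically to image and mask.

    The image is warped bilinearly (reflect padding); the mask is warped as an
    integer class raster with order-0 interpolation and soil fill, then
    re-encoded, so the output mask remains palette-pure.
    """
    if spec.op_name in ("rotation", "zoom", "shear") and spec.magnitude == 0:
        return replace(sample)
    if spec.op_name == "zoom" and spec.magnitude == 1:
        return replace(sample)
    tf = _transform_for(spec, sample.image.shape)
    inv = tf.inverse
    img = warp(sample.image.astype(np.float64), inv, order=1, mode="reflect",
               preserve_range=True)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    classes = mask_to_classes(sample.mask, sample.source_scheme, snap=False)
    soil_cls = SOIL if sample.source_scheme == "unified" else 2
    warped = warp(classes.astype(np.float64), inv, order=0, mode="constant",
                  cval=soil_cls, preserve_range=True).astype(np.int64)
    mask = classes_to_mask(warped, sample.source_scheme)
    return replace(sample, image=img, mask=mask)


def random_spec(rng):
    op = AUGMENTATION_OPS[int(rng.integers(len(AUGMENTATION_OPS)))]
    lo, hi = MAGNITUDE_RANGES[op]
    return AugmentationSpec(op, float(rng.uniform(lo, hi)))


def _augmented_copy(sample, rng, copy_id):
    out = sample
    for _ in range(int(rng.integers(1, 3))):
        out = augment_pair(out, random_spec(rng))
    return replace(out, sample_id=f"{sample.sample_id}_aug{copy_id:05d}")


def resample_to_target(bundle, plan=ResamplePlan(), seed=0):
    """Bring each crop's split to the plan's target count.

    Upsampling keeps all originals and appends augmented copies (cycling over
    the originals); downsampling draws a uniform subset without replacement.
    """
    target = plan.target_test if bundle.split_tag == "test" else plan.target_train
    if plan.direction == "none":
        return bundle
    rng = np.random.default_rng(seed)
    out = []
    for crop in CROPS:
        samples = [s for s in bundle.samples if s.crop_id == crop]
        if not samples:
            continue
        n = len(samples)
        direction = plan.direction
        if direction == "auto":
            direction = "upsample" if n < target else "downsample" if n > target else "keep"
        if direction == "upsample":
            if target < n:
                raise ValueError(f"{crop}: cannot upsample {n} -> {target}")
            out.extend(samples)
            for j in range(target - n):
                out.append(_augmented_copy(samples[j % n], rng, j))
        elif direction == "downsample":
            if target > n:
                raise ValueError(f"{crop}: cannot downsample {n} -> {target}")
            keep = np.sort(rng.choice(n, size=target, replace=False))
            out.extend(samples[i] for i in keep)
        else:
            out.extend(samples)
    return DatasetBundle(out, split_tag=bundle.split_tag)


def make_cv_folds(bundle, k=5, seed=0):
    """k-fold CV partition, stratified by crop; returns [(train, val), ...]."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(bundle) < k:
        raise ValueError(f"bundle of {len(bundle)} samples cannot form {k} folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(bundle), dtype=np.int64)
    for crop in CROPS:
        idx = np.array([i for i, s in enumerate(bundle.samples) if s.crop_id == crop])
        if idx.size == 0:
            continue
        perm = rng.permutation(idx.size)
        fold_of[idx[perm]] = np.arange(idx.size) % k
    folds = []
    for f in range(k):
        val = [i for i in range(len(bundle)) if fold_of[i] == f]
        train = [i for i in range(len(bundle)) if fold_of[i] != f]
        folds.append((bundle.subset(train, f"fold-{f}-train"),
                      bundle.subset(val, f"fold-{f}-val")))
    return folds
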