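"""Synthetic crop-field image/mask generator.

Emulates the statistical structure of the three field datasets the segmentation
model is aimed at: soil-dominated scenes (~94% of pixels are background soil),
one crop species per image drawn as morphologically distinct canopies, and a
scatter of small irregular weeds.  Masks are perfect ground truth drawn in the
unified palette, so every downstream stage (codec, augmentation, training,
metrics) is exercisable offline and deterministically.

Crop morphologies are designed to be separable by shape:

* carrot    - thin feathery multi-lobe rosettes,
* sugar_beet - broad paired ellipses,
* sunflower - large round blobs with radial lobes,
* weed      - small irregular blobs scattered off the crop row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .palettes import SOIL, UNIFIED, classes_to_mask, get_palette, mask_to_classes

CROPS = ("carrot", "sugar_beet", "sunflower")
#: unified class index of each crop species
CROP_CLASS = {"carrot": 0, "sugar_beet": 1, "sunflower": 2}
WEED_CLASS = 3

_SOIL_RGB = np.array([118.0, 86.0, 58.0])
_PLANT_RGB = {
    0: np.array([46.0, 104.0, 42.0]),   # carrot foliage: dark green
    1: np.array([62.0, 142.0, 58.0]),   # sugar beet: mid green
    2: np.array([78.0, 152.0, 50.0]),   # sunflower: yellow-green
    WEED_CLASS: np.array([66.0, 124.0, 46.0]),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic scene generator.

    ``soil_fraction_target`` sets the expected background share; blob areas are
    budgeted from it so the realized mean soil fraction tracks the target.
    """

    image_size: int = 224
    soil_fraction_target: float = 0.94
    crops_per_image: tuple = (1, 3)
    weeds_per_image: tuple = (2, 5)
    crop_shape_params: dict = field(default_factory=dict)
    noise_level: float = 7.0
    seed: int = 0
    boundary_jitter: bool = False

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 < self.soil_fraction_target < 1.0:
            raise ValueError("soil_fraction_target must lie in (0, 1)")


@dataclass
class SegSample:
    """A field image paired with its label mask and provenance."""

    image: np.ndarray  # HxWx3 uint8
    mask: np.ndarray   # HxWx3 uint8, exact palette colors
    crop_id: str
    source_scheme: str = "unified"
    sample_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError("image and mask must share spatial extent")


@dataclass
class DatasetBundle:
    """An ordered collection of samples with a split tag."""

    samples: list
    split_tag: str = "train"

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique within a bundle")

    def __len__(self):
        return len(self.samples)

    @property
    def per_crop_counts(self):
        counts = {}
        for s in self.samples:
            counts[s.crop_id] = counts.get(s.crop_id, 0) + 1
        return counts

    def subset(self, indices, split_tag=None):
        return DatasetBundle([self.samples[i] for i in indices],
                             split_tag or self.split_tag)


def _ellipse(classes, cls, cx, cy, a, b, theta, lobes=0, lobe_amp=0.0, phase=0.0):
    """Paint a (possibly radially-lobed) ellipse onto the class raster."""
    S = classes.shape[0]
    r = int(np.ceil(max(a, b) * (1 + lobe_amp))) + 1
    y0, y1 = max(0, int(cy) - r), min(S, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(S, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    c, s = np.cos(theta), np.sin(theta)
    u = (c * dx + s * dy) / max(a, 1e-6)
    v = (-s * dx + c * dy) / max(b, 1e-6)
    rr = np.sqrt(u * u + v * v)
    boundary = 1.0
    if lobes:
        boundary = 1.0 + lobe_amp * np.sin(lobes * np.arctan2(v, u) + phase)
    classes[y0:y1, x0:x1][rr <= boundary] = cls


def _draw_crop(classes, crop_cls, cx, cy, area, rng, shape_params):
    """Draw one crop canopy of roughly ``area`` pixels centred at (cx, cy)."""
    if crop_cls == 0:  # carrot: feathery rosette of thin lobes
        n = int(shape_params.get("carrot_lobes", rng.integers(6, 10)))
        aspect = shape_params.get("carrot_aspect", 0.28)
        a = np.sqrt(area / (n * np.pi * aspect * 0.9))
        for i in range(n):
            ang = 2 * np.pi * i / n + rng.normal(0, 0.15)
            off = a * 0.55
            _ellipse(classes, crop_cls, cx + off * np.cos(ang), cy + off * np.sin(ang),
                     a, aspect * a, ang)
    elif crop_cls == 1:  # sugar beet: broad paired ellipses
        aspect = shape_params.get("beet_aspect", 0.62)
        a = np.sqrt(area / (2 * np.pi * aspect))
        ang = rng.uniform(0, np.pi)
        for sgn in (-1, 1):
            _ellipse(classes, crop_cls,
                     cx + sgn * 0.75 * a * np.cos(ang), cy + sgn * 0.75 * a * np.sin(ang),
                     a, aspect * a, ang + rng.normal(0, 0.1))
    else:  # sunflower: big round blob with radial lobes
        lobes = int(shape_params.get("sunflower_lobes", 8))
        r = np.sqrt(area / np.pi)
        _ellipse(classes, crop_cls, cx, cy, r, r, 0.0,
                 lobes=lobes, lobe_amp=0.22, phase=rng.uniform(0, 2 * np.pi))
    classes[int(np.clip(cy, 0, classes.shape[0] - 1)),
            int(np.clip(cx, 0, classes.shape[1] - 1))] = crop_cls


def _draw_weed(classes, cx, cy, area, rng):
    n = rng.integers(2, 4)
    a = np.sqrt(area / (n * np.pi * 0.5))
    for _ in range(n):
        _ellipse(classes, WEED_CLASS,
                 cx + rng.normal(0, 0.6 * a), cy + rng.normal(0, 0.6 * a),
                 a * rng.uniform(0.7, 1.3), 0.5 * a * rng.uniform(0.7, 1.3),
                 rng.uniform(0, np.pi))
    classes[int(np.clip(cy, 0, classes.shape[0] - 1)),
            int(np.clip(cx, 0, classes.shape[1] - 1))] = WEED_CLASS


def _render_image(classes, rng, config):
    S = config.image_size
    low = gaussian_filter(rng.standard_normal((S, S)), sigma=max(2.0, S / 28.0))
    low /= max(low.std(), 1e-8)
    img = _SOIL_RGB[None, None, :] * (1.0 + 0.16 * low)[..., None]
    img += rng.normal(0, 4.0, size=(S, S, 3))  # fine soil grain

    veg = classes != SOIL
    if veg.any():
        tex = gaussian_filter(rng.standard_normal((S, S)), sigma=1.5)
        tex /= max(tex.std(), 1e-8)
        plant = np.zeros_like(img)
        for cls, rgb in _PLANT_RGB.items():
            sel = classes == cls
            if sel.any():
                plant[sel] = rgb[None, :] * (1.0 + 0.20 * tex[sel])[:, None]
        img[veg] = plant[veg]
    img += rng.normal(0, config.noise_level, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_field_sample(config, crop_id, seed):
    """Generate one image/mask pair for ``crop_id``; deterministic in
    ``(config, crop_id, seed)``."""
    if crop_id not in CROPS:
        raise ValueError(f"unknown crop_id {crop_id!r}; choose from {CROPS}")
    crop_cls = CROP_CLASS[crop_id]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), crop_cls, int(seed))))
    S = config.image_size
    classes = np.full((S, S), SOIL, dtype=np.int64)

    veg_budget = (1.0 - config.soil_fraction_target) * S * S
    c_lo, c_hi = config.crops_per_image
    w_lo, w_hi = config.weeds_per_image
    mean_crops = max((c_lo + c_hi) / 2.0, 1e-9)
    mean_weeds = max((w_lo + w_hi) / 2.0, 1e-9)
    crop_area = 0.72 * veg_budget / mean_crops
    weed_area = 0.28 * veg_budget / mean_weeds

    n_crops = int(rng.integers(c_lo, c_hi + 1))
    n_weeds = int(rng.integers(w_lo, w_hi + 1))
    # Crops sit on a loose row; weeds scatter anywhere off the row.
    row_y = rng.uniform(0.25, 0.75) * S
    margin = 0.12 * S
    for i in range(n_crops):
        cx = (i + rng.uniform(0.3, 0.7)) * S / max(n_crops, 1)
        cy = row_y + rng.normal(0, 0.04 * S)
        cx, cy = np.clip(cx, margin, S - margin), np.clip(cy, margin, S - margin)
        _draw_crop(classes, crop_cls, cx, cy, crop_area * rng.uniform(0.7, 1.3),
                   rng, config.crop_shape_params)
    for _ in range(n_weeds):
        cx = rng.uniform(margin / 2, S - margin / 2)
        cy = rng.uniform(margin / 2, S - margin / 2)
        if abs(cy - row_y) < 0.08 * S:  # push weeds off the crop row
            cy = (cy + 0.25 * S) % S
        _draw_weed(classes, cx, cy, weed_area * rng.uniform(0.6, 1.4), rng)

    if config.boundary_jitter:
        flips = rng.random(classes.shape) < 0.02
        edge = classes != np.roll(classes, 1, axis=0)
        classes[flips & edge] = SOIL

    image = _render_image(classes, rng, config)
    mask = classes_to_mask(classes, UNIFIED)
    return SegSample(image=image, mask=mask, crop_id=crop_id,
                     source_scheme="unified", sample_id=f"{crop_id}_s{int(seed)}")


def generate_dataset(config, counts, seed=0):
    """Generate a bundle with exactly the requested per-crop counts.

    ``counts`` maps crop_id -> number of samples, e.g. the three source
    datasets' actual sizes ``{"carrot": 60, "sugar_beet": 1800, "sunflower": 146}``.
    """
    samples = []
    for crop_id in CROPS:
        n = int(counts.get(crop_id, 0))
        if n < 0:
            raise ValueError(f"count for {crop_id!r} must be >= 0, got {n}")
        for i in range(n):
            sub = int(np.random.SeedSequence(
                entropy=(int(seed), CROP_CLASS[crop_id], i)).generate_state(1)[0])
            s = generate_field_sample(config, crop_id, sub)
            s.sample_id = f"{crop_id}_{i:05d}"
            samples.append(s)
    return DatasetBundle(samples, split_tag="all")


_SOIL_CLASS_BY_SCHEME = {"unified": 4, "cwfid": 2, "sugar_beet": 2, "sunflower": 2}


def soil_fraction(sample):
    """Fraction of mask pixels labeled soil, in [0, 1].

    Raises (via the codec) on any pixel that is not an exact palette color.
    """
    palette = get_palette(sample.source_scheme)
    classes = mask_to_classes(sample.mask, palette, snap=False)
    return float((classes == _SOIL_CLASS_BY_SCHEME[sample.source_scheme]).mean())


def save_bundle(bundle, out_dir):
    """Write images/, masks/ and a manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in bundle.samples:
        Image.fromarray(s.image).save(out / "images" / f"{s.sample_id}.png")
        Image.fromarray(s.mask).save(out / "masks" / f"{s.sample_id}.png")
        manifest.append({"sample_id": s.sample_id, "crop_id": s.crop_id,
                         "split_tag": bundle.split_tag, "scheme": s.source_scheme})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(in_dir, split_tag=None):
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = []
    tag = split_tag
    for rec in manifest:
        if split_tag is not None and rec["split_tag"] != split_tag:
            continue
        tag = rec["split_tag"] if split_tag is None else split_tag
        samples.append(SegSample(
            image=np.asarray(Image.open(src / "images" / f"{rec['sample_id']}.png").convert("RGB")),
            mask=np.asarray(Image.open(src / "masks" / f"{rec['sample_id']}.png").convert("RGB")),
            crop_id=rec["crop_id"], source_scheme=rec["scheme"],
            sample_id=rec["sample_id"]))
    return DatasetBundle(samples, split_tag=tag or "all")
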