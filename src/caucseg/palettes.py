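"""Color palettes and label codecs for crop/weed segmentation masks.

Masks arrive in one of three source annotation schemes (each dataset paints
crop/weed/soil differently) and are harmonized into a single unified palette:
carrot = blue, sugar beet = green, sunflower = turquoise, weed = red,
soil = black.  Pixel classes follow the fixed map
``{carrot, sugar_beet, sunflower, weed, soil} = {0, 1, 2, 3, 4}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("carrot", "sugar_beet", "sunflower", "weed", "soil")
NUM_CLASSES = 5
SOIL = 4

#: Euclidean RGB distance within which off-palette pixels (e.g. compression
#: artifacts in real annotations) snap to the nearest palette color.
SNAP_TOLERANCE = 30.0


@dataclass(frozen=True)
class LabelPalette:
    """A named mapping between RGB triples and class indices."""

    scheme_name: str
    color_to_class: dict = field(default_factory=dict)

    def __post_init__(self):
        classes = sorted(self.color_to_class.values())
        if classes != list(range(len(classes))):
            raise ValueError("class indices must be contiguous from 0")
        if len(set(self.color_to_class)) != len(self.color_to_class):
            raise ValueError("duplicate colors in palette")

    @property
    def class_to_color(self):
        return {v: k for k, v in self.color_to_class.items()}

    @property
    def num_classes(self):
        return len(self.color_to_class)

    def colors(self):
        return np.array(sorted(self.color_to_class, key=self.color_to_class.get),
                        dtype=np.int64)


UNIFIED = LabelPalette("unified", {
    (0, 0, 255): 0,      # carrot (blue)
    (0, 255, 0): 1,      # sugar beet (green)
    (0, 255, 255): 2,    # sunflower (turquoise)
    (255, 0, 0): 3,      # weed (red)
    (0, 0, 0): 4,        # soil (black)
})

# Source schemes are 3-class (crop / weed / soil); their "crop" maps onto the
# scheme's own crop class in the unified palette.
CWFID = LabelPalette("cwfid", {
    (255, 0, 0): 0,      # crop (carrot) marked red
    (0, 255, 0): 1,      # weed marked green
    (0, 0, 0): 2,        # soil
})
SUGAR_BEET = LabelPalette("sugar_beet", {
    (0, 255, 0): 0,      # crop (sugar beet) marked green
    (255, 0, 0): 1,      # weed marked red
    (0, 0, 0): 2,        # soil
})
SUNFLOWER = LabelPalette("sunflower", {
    (0, 255, 0): 0,      # crop (sunflower) marked green
    (255, 0, 0): 1,      # weed marked red
    (0, 0, 0): 2,        # soil
})

PALETTES = {p.scheme_name: p for p in (UNIFIED, CWFID, SUGAR_BEET, SUNFLOWER)}

#: source-class -> unified-class for each 3-class source scheme
_SOURCE_TO_UNIFIED = {
    "cwfid": {0: 0, 1: 3, 2: 4},
    "sugar_beet": {0: 1, 1: 3, 2: 4},
    "sunflower": {0: 2, 1: 3, 2: 4},
}


def get_palette(scheme_name):
    try:
        return PALETTES[scheme_name]
    except KeyError:
        raise ValueError(
            f"unknown palette scheme {scheme_name!r}; choose from {sorted(PALETTES)}"
        ) from None


def mask_to_classes(mask, palette=UNIFIED, snap=True):
    """Decode an RGB mask into an integer class raster.

    Off-palette pixels within ``SNAP_TOLERANCE`` (Euclidean RGB) of a palette
    color are snapped when ``snap`` is true; anything farther raises with the
    offending color and its coordinates.
    """
    if isinstance(palette, str):
        palette = get_palette(palette)
    mask = np.asarray(mask)
    if mask.ndim != 3 or mask.shape[-1] != 3:
        raise ValueError(f"mask must be HxWx3, got shape {mask.shape}")
    colors = palette.colors()  # (M, 3), row i = color of class i
    dist2 = ((mask[:, :, None, :].astype(np.int64) - colors) ** 2).sum(axis=-1)
    classes = dist2.argmin(axis=-1)
    mind2 = np.take_along_axis(dist2, classes[..., None], axis=-1)[..., 0]
    tol2 = 0.0 if not snap else SNAP_TOLERANCE ** 2
    bad = mind2 > tol2
    if bad.any():
        ys, xs = np.nonzero(bad)
        y, x = int(ys[0]), int(xs[0])
        raise ValueError(
            f"mask pixel at (row={y}, col={x}) has color {tuple(int(v) for v in mask[y, x])} "
            f"not in palette {palette.scheme_name!r} (beyond snap tolerance); "
            f"{int(bad.sum())} offending pixel(s) total"
        )
    return classes.astype(np.int64)


def classes_to_mask(raster, palette=UNIFIED):
    """Encode an integer class raster as an RGB mask in ``palette``."""
    if isinstance(palette, str):
        palette = get_palette(palette)
    raster = np.asarray(raster)
    if raster.min() < 0 or raster.max() >= palette.num_classes:
        raise ValueError(f"class index out of range for {palette.num_classes}-class palette")
    lut = palette.colors().astype(np.uint8)
    return lut[raster]


def recolor_mask(mask, source_scheme):
    """Re-paint a source-scheme mask into the unified palette.

    Per-semantic-class pixel counts are preserved: the source's crop class maps
    to that crop's unified color, weed to red, soil to black.
    """
    if source_scheme == "unified":
        classes = mask_to_classes(mask, UNIFIED)
        return classes_to_mask(classes, UNIFIED)
    if source_scheme not in _SOURCE_TO_UNIFIED:
        raise ValueError(
            f"unknown source scheme {source_scheme!r}; "
            f"choose from {sorted(_SOURCE_TO_UNIFIED) + ['unified']}"
        )
    palette = get_palette(source_scheme)
    classes = mask_to_classes(mask, palette)
    lut = np.array([_SOURCE_TO_UNIFIED[source_scheme][c]
                    for c in range(palette.num_classes)], dtype=np.int64)
    return classes_to_mask(lut[classes], UNIFIED)


def classes_to_onehot(raster, num_classes=NUM_CLASSES):
    """(H, W) class raster -> (H, W, M) one-hot volume."""
    raster = np.asarray(raster)
    if raster.min() < 0 or raster.max() >= num_classes:
        raise ValueError(f"class entries must lie in [0, {num_classes})")
    return np.eye(num_classes, dtype=np.float32)[raster]


def prediction_to_mask(prob_volume):
    """Argmax a (H, W, M) probability volume into a unified-palette mask.

    Ties break toward the lowest class index (numpy argmax convention).
    """
    prob_volume = np.asarray(prob_volume)
    if prob_volume.ndim != 3 or prob_volume.shape[-1] != NUM_CLASSES:
        raise ValueError(f"expected HxWx{NUM_CLASSES} probability volume, got {prob_volume.shape}")
    if not np.isfinite(prob_volume).all():
        raise ValueError("probability volume contains non-finite values")
    return classes_to_mask(prob_volume.argmax(axis=-1), UNIFIED)
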