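"""Synthetic field-image generator: determinism, palette closure, soil share."""

import numpy as np
import pytest

from caucseg.palettes import UNIFIED, mask_to_classes
from caucseg.synthetic import (
    CROPS,
    SynthConfig,
    generate_dataset,
    generate_field_sample,
    load_bundle,
    save_bundle,
    soil_fraction,
)

CFG = SynthConfig(image_size=64, seed=0)


class TestFieldSample:
    def test_same_seed_reproduces_byte_identical_output(self):
        a = generate_field_sample(CFG, "carrot", 1)
        b = generate_field_sample(CFG, "carrot", 1)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_different_seeds_differ(self):
        a = generate_field_sample(CFG, "carrot", 1)
        b = generate_field_sample(CFG, "carrot", 2)
        assert not np.array_equal(a.image, b.image)

    def test_mask_contains_only_own_crop_and_weeds(self):
        s = generate_field_sample(CFG, "sunflower", 7)
        colors = {tuple(c) for c in np.unique(s.mask.reshape(-1, 3), axis=0)}
        assert colors <= {(0, 0, 0), (0, 255, 255), (255, 0, 0)}

    @pytest.mark.parametrize("crop", CROPS)
    def test_palette_closure_and_class_presence(self, crop):
        s = generate_field_sample(CFG, crop, 11)
        classes = mask_to_classes(s.mask, UNIFIED, snap=False)  # raises if off-palette
        assert (classes == 3).sum() >= 1, "at least one weed pixel"
        crop_cls = CROPS.index(crop)
        assert (classes == crop_cls).sum() >= 1, "at least one crop pixel"

    def test_plants_green_soil_brown(self):
        s = generate_field_sample(CFG, "sugar_beet", 3)
        classes = mask_to_classes(s.mask)
        veg, soil = classes != 4, classes == 4
        veg_rgb = s.image[veg].mean(axis=0)
        soil_rgb = s.image[soil].mean(axis=0)
        assert veg_rgb[1] > veg_rgb[0] and veg_rgb[1] > veg_rgb[2]  # green-hued
        assert soil_rgb[0] > soil_rgb[2]  # brown-hued

    def test_unknown_crop_names_allowed_set(self):
        with pytest.raises(ValueError, match="carrot"):
            generate_field_sample(CFG, "maize", 0)


class TestSoilFraction:
    def test_all_soil_mask_gives_one(self):
        s = generate_field_sample(CFG, "carrot", 1)
        s.mask = np.zeros_like(s.mask)
        assert soil_fraction(s) == 1.0

    def test_single_nonsoil_pixel(self):
        s = generate_field_sample(SynthConfig(image_size=224), "carrot", 1)
        s.mask = np.zeros_like(s.mask)
        s.mask[0, 0] = (255, 0, 0)
        assert soil_fraction(s) == pytest.approx(1 - 1 / 50176)

    def test_non_palette_pixel_rejected_with_color(self):
        s = generate_field_sample(CFG, "carrot", 1)
        s.mask[0, 0] = (7, 9, 11)
        with pytest.raises(ValueError, match=r"\(7, 9, 11\)"):
            soil_fraction(s)

    def test_default_sample_near_target(self):
        s = generate_field_sample(SynthConfig(), "sugar_beet", 0)
        assert abs(soil_fraction(s) - 0.94) <= 0.05

    def test_mean_soil_fraction_in_band(self):
        cfg = SynthConfig(image_size=96, seed=2)
        fractions = [soil_fraction(generate_field_sample(cfg, crop, s))
                     for crop in CROPS for s in range(15)]
        assert 0.90 <= np.mean(fractions) <= 0.97


class TestDataset:
    def test_requested_per_crop_counts(self):
        b = generate_dataset(SynthConfig(image_size=32), {"carrot": 4, "sunflower": 2}, seed=1)
        assert b.per_crop_counts == {"carrot": 4, "sunflower": 2}
        assert len(b) == 6
        assert len({s.sample_id for s in b.samples}) == 6

    def test_zero_counts_give_empty_bundle(self):
        b = generate_dataset(SynthConfig(image_size=32), {}, seed=1)
        assert len(b) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            generate_dataset(SynthConfig(image_size=32), {"carrot": -1}, seed=1)

    def test_seed_changes_content_not_structure(self):
        b1 = generate_dataset(SynthConfig(image_size=32), {"carrot": 3}, seed=1)
        b2 = generate_dataset(SynthConfig(image_size=32), {"carrot": 3}, seed=2)
        assert b1.per_crop_counts == b2.per_crop_counts
        assert not np.array_equal(b1.samples[0].image, b2.samples[0].image)

    def test_determinism_bytewise(self):
        b1 = generate_dataset(SynthConfig(image_size=32), {"sugar_beet": 2}, seed=9)
        b2 = generate_dataset(SynthConfig(image_size=32), {"sugar_beet": 2}, seed=9)
        for s1, s2 in zip(b1.samples, b2.samples):
            assert np.array_equal(s1.image, s2.image)
            assert np.array_equal(s1.mask, s2.mask)


def test_save_load_roundtrip(tmp_path):
    b = generate_dataset(SynthConfig(image_size=32), {"carrot": 2, "sunflower": 1}, seed=3)
    save_bundle(b, tmp_path)
    loaded = load_bundle(tmp_path)
    assert loaded.per_crop_counts == b.per_crop_counts
    for s1, s2 in zip(b.samples, loaded.samples):
        assert np.array_equal(s1.image, s2.image)
        assert np.array_equal(s1.mask, s2.mask)
        assert s1.sample_id == s2.sample_id


def test_config_invariants():
    with pytest.raises(ValueError):
        SynthConfig(image_size=16)
    with pytest.raises(ValueError):
        SynthConfig(soil_fraction_target=1.0)
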