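import numpy as np
import pytest

from lascakit.errors import (
    ConsistencyError,
    DomainError,
    InsufficientDataError,
    ParameterError,
)
from lascakit.imaging import IntensityImage, RegionSpec
from lascakit.lasca import LascaMap, lasca_map
from lascakit.metrics import (
    SampleMeasurement,
    central_mask,
    contrast_ratio,
    mean_contrast,
    measure_sample,
    region_block_mask,
    summarize_group,
)
from lascakit.synthetic import PhantomConfig, generate_phantom


def map_from_contrast(contrast, valid=None, window=4):
    contrast = np.asarray(contrast, dtype=float)
    if valid is None:
        valid = np.ones_like(contrast, bool)
    mean = np.ones_like(contrast)
    return LascaMap(contrast=contrast, mean=mean, std=contrast * mean,
                    valid=np.asarray(valid, bool), window=window)


class TestCentralMask:
    def test_full_fraction_equals_validity(self, rng):
        valid = rng.uniform(size=(20, 20)) > 0.3
        lmap = map_from_contrast(rng.uniform(size=(20, 20)), valid)
        np.testing.assert_array_equal(central_mask(lmap, 1.0), valid)

    def test_half_fraction_on_175_grid(self):
        lmap = map_from_contrast(np.ones((175, 175)))
        mask = central_mask(lmap, 0.5)
        assert mask.sum() == 88 * 88
        rows = np.flatnonzero(mask.any(axis=1))
        assert rows[0] == (175 - 88) // 2 == 43
        assert rows[-1] == 43 + 88 - 1

    def test_all_invalid_gives_empty_mask(self):
        lmap = map_from_contrast(np.ones((10, 10)), np.zeros((10, 10), bool))
        assert not central_mask(lmap, 0.5).any()

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_validated(self, fraction):
        with pytest.raises(ParameterError):
            central_mask(map_from_contrast(np.ones((4, 4))), fraction)


class TestMeanContrast:
    def test_constant_region(self):
        lmap = map_from_contrast(np.full((10, 10), 0.5))
        region = RegionSpec("sound", 0, 0, 40, 40)  # pixel coords, window 4
        value, n = mean_contrast(lmap, region, np.ones((10, 10), bool), min_cells=5)
        assert value == 0.5 and n == 100

    def test_invalid_cells_excluded_from_mean(self):
        contrast = np.array([[0.2, 0.4, 0.9]])
        valid = np.array([[True, True, False]])
        lmap = map_from_contrast(contrast, valid)
        region = RegionSpec("lesion", 0, 0, 4, 12)
        value, n = mean_contrast(lmap, region, np.ones((1, 3), bool), min_cells=2)
        assert value == pytest.approx(0.3) and n == 2

    def test_region_outside_mask_is_insufficient(self):
        lmap = map_from_contrast(np.ones((10, 10)))
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        region = RegionSpec("sound", 24, 0, 40, 40)  # block rows 6..9
        with pytest.raises(InsufficientDataError):
            mean_contrast(lmap, region, mask, min_cells=1)

    def test_block_inclusion_by_top_left_pixel(self):
        lmap = map_from_contrast(np.ones((4, 4)))
        # region [2, 6) px with window 4 contains only block col 1 (pixel 4)
        region = RegionSpec("sound", 0, 2, 16, 6)
        sel = region_block_mask(lmap, region)
        assert np.array_equal(np.flatnonzero(sel.any(axis=0)), [1])


class TestContrastRatio:
    @pytest.mark.parametrize("cs,cl,expected", [
        (0.8, 0.8, 0.0),
        (0.5, 1.0, 0.5),
        (0.82, 1.0, 0.18),
    ])
    def test_algebra(self, cs, cl, expected):
        assert contrast_ratio(cs, cl) == pytest.approx(expected)

    def test_signed_when_reversed(self):
        assert contrast_ratio(1.0, 0.5) == pytest.approx(-1.0)

    def test_label_swap_relation(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 2.0, 2)
            cr = contrast_ratio(a, b)
            swapped = contrast_ratio(b, a)
            assert swapped == pytest.approx(1.0 - 1.0 / (1.0 - cr), rel=1e-12)
        assert contrast_ratio(0.7, 0.7) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            contrast_ratio(0.0, 1.0)
        with pytest.raises(DomainError):
            contrast_ratio(1.0, -0.2)


class TestMeasureSample:
    def test_null_phantom_near_zero(self):
        config = PhantomConfig(height=256, width=256, grain=1.5, boundary_col=128,
                               mean_sound=100, mean_lesion=100,
                               n_sum_sound=2, n_sum_lesion=2, seed=7)
        image, lesion, sound = generate_phantom(config)
        m = measure_sample(image, sound, lesion)
        assert abs(m.contrast_ratio) < 0.03

    def test_graded_phantom_recovers_half(self):
        config = PhantomConfig(height=256, width=256, grain=1.5, boundary_col=128,
                               n_sum_sound=4, n_sum_lesion=1, seed=3)
        image, lesion, sound = generate_phantom(config)
        m = measure_sample(image, sound, lesion)
        assert m.contrast_ratio == pytest.approx(0.5, abs=0.05)
        assert m.n_valid_sound >= 25 and m.n_valid_lesion >= 25

    def test_intensity_rescale_leaves_measurement_unchanged(self):
        config = PhantomConfig(height=128, width=128, grain=1.5, boundary_col=64, seed=5)
        image, lesion, sound = generate_phantom(config)
        m1 = measure_sample(image, sound, lesion)
        m2 = measure_sample(IntensityImage(image.pixels * 37.5), sound, lesion)
        assert m2.c_sound == pytest.approx(m1.c_sound, rel=1e-9)
        assert m2.contrast_ratio == pytest.approx(m1.contrast_ratio, rel=1e-9)

    def test_constant_image_is_domain_error(self):
        img = IntensityImage(np.full((128, 128), 9.0))
        sound = RegionSpec("sound", 0, 64, 128, 128)
        lesion = RegionSpec("lesion", 0, 0, 128, 64)
        with pytest.raises(DomainError):
            measure_sample(img, sound, lesion, fraction=1.0)

    def test_overlapping_regions_rejected(self, rng):
        img = IntensityImage(rng.uniform(1, 10, (64, 64)))
        with pytest.raises(ConsistencyError):
            measure_sample(img, RegionSpec("sound", 0, 0, 64, 40),
                           RegionSpec("lesion", 0, 30, 64, 64))


class TestSummarizeGroup:
    @staticmethod
    def sample(cr, duration=10.0, sid="s"):
        return SampleMeasurement(sample_id=sid, group_duration=duration,
                                 c_sound=0.5, c_lesion=0.5 / (1 - cr),
                                 contrast_ratio=cr, n_valid_sound=100, n_valid_lesion=100)

    def test_single_sample_has_no_sd(self):
        s = summarize_group([self.sample(0.2)], 10.0)
        assert s.n == 1 and s.mean_cr == 0.2 and s.sd_cr is None

    def test_mean_and_sample_sd(self):
        g = summarize_group([self.sample(cr, sid=str(cr)) for cr in (0.1, 0.2, 0.3)], 10.0)
        assert g.mean_cr == pytest.approx(0.2)
        assert g.sd_cr == pytest.approx(0.1)

    def test_mixed_durations_rejected(self):
        with pytest.raises(ConsistencyError):
            summarize_group([self.sample(0.1, 10.0, "a"), self.sample(0.2, 20.0, "b")], 10.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            summarize_group([], 10.0)
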