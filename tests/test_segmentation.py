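"""Stiffness-map rendering, ECM segmentation and region statistics."""

import numpy as np
import pytest

from cardioafm.curves import DataError
from cardioafm.maps import StiffnessMap
from cardioafm.segmentation import (correct_height_offset_linewise,
                                    isolate_region_values,
                                    render_stiffness_image, segment_ecm_direct,
                                    segment_ecm_image)
from cardioafm.synthetic import gen_stiffness_map


def _two_level_map(n=32, frac=0.25, lo=5e3, hi=25e3):
    e = np.full((n, n), lo)
    k = int(frac * n * n)
    e.flat[:k] = hi
    return StiffnessMap(x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
                        modulus=e)


class TestRendering:
    def test_uniform_map_single_colour(self):
        m = _two_level_map(frac=0.0)
        img = render_stiffness_image(m, value_range=(0.0, 1e4))
        assert np.unique(img.rgb.reshape(-1, 3), axis=0).shape[0] == 1

    def test_two_level_map_two_colours(self):
        img = render_stiffness_image(_two_level_map())
        assert np.unique(img.rgb.reshape(-1, 3), axis=0).shape[0] == 2

    def test_degenerate_range_rejected(self):
        with pytest.raises(DataError):
            render_stiffness_image(_two_level_map(frac=0.0))


class TestImageSpaceSegmentation:
    def test_all_black_empty_mask(self):
        from cardioafm.maps import LabeledImage
        img = LabeledImage(rgb=np.zeros((8, 8, 3), np.uint8))
        assert not segment_ecm_image(img, threshold=0.5).any()

    def test_fixed_threshold_half_split(self):
        from cardioafm.maps import LabeledImage
        rgb = np.zeros((10, 10, 3), np.uint8)
        rgb[:5, :, 1] = 200
        rgb[5:, :, 1] = 20
        img = LabeledImage(rgb=rgb)
        mask = segment_ecm_image(img, threshold=100 / 255)
        assert mask.mean() == pytest.approx(0.5)

    def test_otsu_separates_bimodal(self):
        m = _two_level_map(frac=0.3)
        mask = segment_ecm_image(render_stiffness_image(m), threshold="otsu")
        assert mask.mean() == pytest.approx((m.modulus > 1e4).mean(), abs=0)


class TestValueSpaceSegmentation:
    def test_threshold_below_min_full_mask(self):
        m = _two_level_map()
        assert segment_ecm_direct(m, threshold=1.0).all()

    def test_cross_method_equivalence_two_level(self):
        m = _two_level_map(frac=0.3)
        img_mask = segment_ecm_image(render_stiffness_image(m))
        val_mask = segment_ecm_direct(m)
        np.testing.assert_array_equal(img_mask, val_mask)

    def test_fraction_monotone_in_threshold(self):
        m, _ = gen_stiffness_map(0.3, shape=(64, 64), seed=0)
        fracs = [segment_ecm_direct(m, threshold=t).mean()
                 for t in (1e3, 8e3, 15e3, 40e3)]
        assert fracs == sorted(fracs, reverse=True)

    def test_missing_pixels_never_in_mask(self):
        m, _ = gen_stiffness_map(0.3, shape=(64, 64), missing_fraction=0.05, seed=1)
        mask = segment_ecm_direct(m)
        assert not (mask & ~m.valid).any()


class TestRegionValues:
    def test_full_mask_identity(self):
        m, _ = gen_stiffness_map(0.3, shape=(64, 64), seed=2)
        res = isolate_region_values(m, np.ones(m.shape, bool))
        assert res.summary["ECM"]["mean"] == pytest.approx(np.nanmean(m.modulus))
        assert res.ecm_fraction == 1.0

    def test_empty_mask_sentinel(self):
        m, _ = gen_stiffness_map(0.3, shape=(32, 32), seed=3)
        res = isolate_region_values(m, np.zeros(m.shape, bool))
        assert res.ecm_values.size == 0
        assert res.ecm_fraction == 0.0
        assert np.isnan(res.summary["ECM"]["median"])

    def test_ground_truth_recovery(self):
        m, truth = gen_stiffness_map(0.30, shape=(128, 128), seed=4)
        mask = segment_ecm_direct(m)
        res = isolate_region_values(m, mask)
        assert res.ecm_fraction == pytest.approx(0.30, abs=0.02)
        assert res.summary["ECM"]["median"] == pytest.approx(25e3, rel=0.05)
        assert (mask == truth["ecm_mask"]).mean() >= 0.98

    def test_summary_matches_bruteforce_and_fractions_complement(self):
        m, _ = gen_stiffness_map(0.3, shape=(64, 64), missing_fraction=0.02, seed=5)
        mask = segment_ecm_direct(m)
        res = isolate_region_values(m, mask)
        vals = sorted(res.ecm_values)
        assert res.summary["ECM"]["n"] == len(vals)
        assert res.summary["ECM"]["median"] == pytest.approx(np.median(vals), rel=0)
        assert res.summary["ECM"]["mean"] == pytest.approx(sum(vals) / len(vals), rel=1e-12)
        bg_frac = res.background_values.size / m.valid.sum()
        assert res.ecm_fraction + bg_frac == pytest.approx(1.0, abs=1e-12)

    def test_exclusion_mask_removes_pixels(self):
        m, _ = gen_stiffness_map(0.3, shape=(32, 32), seed=6)
        excl = np.zeros(m.shape, bool)
        excl[:16] = True
        res = isolate_region_values(m, np.ones(m.shape, bool), exclusion=excl)
        assert res.ecm_values.size == 16 * 32

    def test_shape_mismatch_rejected(self):
        m, _ = gen_stiffness_map(0.3, shape=(16, 16), seed=0)
        with pytest.raises(DataError):
            isolate_region_values(m, np.ones((8, 8), bool))


class TestHeightCorrection:
    def _map_with_height(self, height):
        n = height.shape
        return StiffnessMap(x=np.arange(n[1], dtype=float),
                            y=np.arange(n[0], dtype=float),
                            modulus=np.full(n, 5e3), height=height)

    def test_constant_offsets_removed_exactly(self):
        offsets = np.arange(10)[:, None] * 1e-8
        m = self._map_with_height(np.zeros((10, 12)) + offsets)
        out = correct_height_offset_linewise(m, mode="median")
        np.testing.assert_allclose(out.height, 0.0, atol=1e-12)

    def test_modulus_untouched(self):
        m = self._map_with_height(np.random.default_rng(0).normal(0, 1e-8, (6, 6)))
        out = correct_height_offset_linewise(m)
        np.testing.assert_array_equal(out.modulus, m.modulus)

    def test_linear_tilt_removed_by_linear_mode(self):
        xs = np.arange(20, dtype=float)
        tilt = 3e-9 * xs[None, :] + np.arange(5)[:, None] * 1e-8
        out = correct_height_offset_linewise(self._map_with_height(tilt), mode="linear")
        np.testing.assert_allclose(out.height, 0.0, atol=1e-12)

    def test_missing_height_rejected(self):
        m, _ = gen_stiffness_map(0.3, shape=(8, 8), seed=0)
        with pytest.raises(DataError):
            correct_height_offset_linewise(m)
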