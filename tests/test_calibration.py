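"""Calibration: HSV range derivation, body metrics, analysis crop."""

import numpy as np
import pytest
from skimage.color import rgb2hsv

from cagewatch.calibration import (crop_region_a, derive_body_metrics,
                                   derive_hsv_range, frame_to_hsv)
from cagewatch.config import (CalibrationProfile, ConfigError, CropSpec,
                              HsvRange, RectSpec)


def _img(rgb_rows):
    """Float RGB image from a nested list of (r, g, b) rows."""
    return np.asarray(rgb_rows, dtype=np.float64)


def _hue_bounded_image(seed, shape):
    """Random RGB image whose hues stay inside [0.2, 0.5] (no wraparound)."""
    from skimage.color import hsv2rgb
    rng = np.random.default_rng(seed)
    hsv = np.stack([rng.uniform(0.2, 0.5, shape),
                    rng.uniform(0.3, 0.9, shape),
                    rng.uniform(0.3, 0.9, shape)], axis=-1)
    return hsv2rgb(hsv)


class TestFrameToHsv:
    def test_matches_reference_conversion(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(40, 30, 3), dtype=np.uint8)
        ours = frame_to_hsv(img)
        ref = rgb2hsv(img.astype(np.float64) / 255.0)
        assert np.allclose(ours, ref, atol=1e-5)

    def test_rejects_non_color_input(self):
        with pytest.raises(ConfigError):
            frame_to_hsv(np.zeros((5, 5)))


class TestDeriveHsvRange:
    def test_uniform_patch_collapses_to_single_color(self):
        # RGB (0.4, 0.3, 0.2) -> HSV (1/12, 0.5, 0.4) analytically
        img = _img([[[0.4, 0.3, 0.2]] * 4] * 3)
        r = derive_hsv_range(img, RectSpec((0, 0), (4, 3)), pad=0.0)
        assert r.h_min == pytest.approx(r.h_max) == pytest.approx(1 / 12)
        assert r.s_min == pytest.approx(r.s_max) == pytest.approx(0.5)
        assert r.v_min == pytest.approx(r.v_max) == pytest.approx(0.4)

    def test_two_color_patch_gives_channelwise_envelope(self):
        img = _img([[[0.4, 0.3, 0.2], [0.5, 0.45, 0.1]]])
        r = derive_hsv_range(img, RectSpec((0, 0), (2, 1)), pad=0.0)
        # brute-force oracle: min/max over the explicit pixel list
        hsv = rgb2hsv(img).reshape(-1, 3)
        lo, hi = hsv.min(axis=0), hsv.max(axis=0)
        assert (r.h_min, r.s_min, r.v_min) == pytest.approx(tuple(lo), abs=1e-6)
        assert (r.h_max, r.s_max, r.v_max) == pytest.approx(tuple(hi), abs=1e-6)

    def test_pad_widens_each_side_then_clips(self):
        img = _hue_bounded_image(1, (6, 6))
        rect = RectSpec((1, 1), (5, 5))
        base = derive_hsv_range(img, rect, pad=0.0)
        padded = derive_hsv_range(img, rect, pad=0.05)
        for ch in "hsv":
            lo0, hi0 = getattr(base, f"{ch}_min"), getattr(base, f"{ch}_max")
            lo1, hi1 = getattr(padded, f"{ch}_min"), getattr(padded, f"{ch}_max")
            assert lo1 == pytest.approx(max(0.0, lo0 - 0.05), abs=1e-9)
            assert hi1 == pytest.approx(min(1.0, hi0 + 0.05), abs=1e-9)

    def test_every_rect_pixel_lies_inside_range(self):
        img = _hue_bounded_image(2, (10, 12))
        rect = RectSpec((2, 3), (9, 8))
        r = derive_hsv_range(img, rect, pad=0.0)
        hsv = frame_to_hsv(img)[3:8, 2:9].reshape(-1, 3)
        assert (hsv[:, 0] >= r.h_min - 1e-9).all() and (hsv[:, 0] <= r.h_max + 1e-9).all()
        assert (hsv[:, 1] >= r.s_min - 1e-9).all() and (hsv[:, 1] <= r.s_max + 1e-9).all()
        assert (hsv[:, 2] >= r.v_min - 1e-9).all() and (hsv[:, 2] <= r.v_max + 1e-9).all()

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(3)
        img = _hue_bounded_image(3, (1, 16))
        shuffled = img[:, rng.permutation(16)]
        r1 = derive_hsv_range(img, RectSpec((0, 0), (16, 1)))
        r2 = derive_hsv_range(shuffled, RectSpec((0, 0), (16, 1)))
        assert r1.as_tuple() == pytest.approx(r2.as_tuple())

    def test_scaled_output(self):
        img = _img([[[0.4, 0.3, 0.2]]])
        r = derive_hsv_range(img, RectSpec((0, 0), (1, 1)), scale="opencv")
        assert r.h_max == pytest.approx(180 / 12)
        assert r.s_max == pytest.approx(0.5 * 255)
        assert r.v_max == pytest.approx(0.4 * 255)

    def test_hue_wraparound_rejected(self):
        # two reds straddling hue 0: spread > half the hue scale
        img = _img([[[1.0, 0.0, 0.1], [1.0, 0.1, 0.0]]])
        with pytest.raises(ConfigError, match="wrap"):
            derive_hsv_range(img, RectSpec((0, 0), (2, 1)))

    @pytest.mark.parametrize("rect", [
        RectSpec((0, 0), (0, 1)),             # empty
        RectSpec((0, 0), (7, 1)),             # out of bounds
        RectSpec((-1, 0), (2, 1)),            # negative corner
    ])
    def test_bad_rectangles_rejected(self, rect):
        img = _img([[[0.5, 0.5, 0.5]] * 5])
        with pytest.raises(ConfigError):
            derive_hsv_range(img, rect)


class TestDeriveBodyMetrics:
    def test_full_body_rectangle(self):
        # the published whole-animal rectangle: 680 x 150 px
        ax, ay, alpha = derive_body_metrics(RectSpec((0, 0), (680, 150)),
                                            area_fraction=0.1)
        assert (ax, ay) == (680.0, 150.0)
        assert alpha == pytest.approx(10200.0)

    @pytest.mark.parametrize("frac,expect", [(1.0, 100.0), (0.5, 50.0)])
    def test_area_fraction_scaling(self, frac, expect):
        assert derive_body_metrics(RectSpec((0, 0), (10, 10)), frac)[2] \
            == pytest.approx(expect)

    def test_degenerate_rect_and_bad_fraction(self):
        with pytest.raises(ConfigError):
            derive_body_metrics(RectSpec((3, 3), (3, 9)))
        with pytest.raises(ConfigError):
            derive_body_metrics(RectSpec((0, 0), (5, 5)), area_fraction=0.0)


class TestCropRegionA:
    def test_published_crop_geometry(self):
        frame = np.zeros((1080, 1920, 3), dtype=np.uint8)
        out = crop_region_a(frame, CropSpec(mx=350, my=0, rx=1370, ry=880))
        assert out.shape == (880, 1370, 3)

    def test_identity_crop(self):
        frame = np.arange(60, dtype=np.uint8).reshape(4, 5, 3)
        out = crop_region_a(frame, CropSpec(0, 0, 5, 4))
        assert np.array_equal(out, frame)

    def test_coordinate_shift_round_trip(self):
        rng = np.random.default_rng(4)
        frame = rng.integers(0, 255, (50, 60, 3), dtype=np.uint8)
        crop = CropSpec(7, 11, 20, 30)
        out = crop_region_a(frame, crop)
        assert np.array_equal(out[5, 9], frame[11 + 5, 7 + 9])

    def test_out_of_bounds_crop_rejected(self):
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(ConfigError):
            crop_region_a(frame, CropSpec(0, 0, 101, 50))


class TestProfileSerialization:
    def _profile(self):
        return CalibrationProfile(
            body_range=HsvRange(0.1, 0.3, 0.2, 0.6, 0.3, 0.7),
            eye_range=HsvRange(0.5, 0.7, 0.1, 0.5, 0.05, 0.25),
            ax=680, ay=150, alpha_th=10200,
            crop=CropSpec(350, 0, 1370, 880), fps=60.0)

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, tmp_path, suffix):
        p = self._profile()
        path = tmp_path / f"profile{suffix}"
        p.save(path)
        q = CalibrationProfile.load(path)
        assert q.to_dict() == pytest.approx(p.to_dict())

    def test_swapped_threshold_pairs_are_sorted_on_load(self):
        # published listings sometimes print min/max swapped (e.g. v 75/125)
        d = self._profile().to_dict()
        d["body.v_min"], d["body.v_max"] = 125.0, 75.0
        q = CalibrationProfile.from_dict(d)
        assert (q.body_range.v_min, q.body_range.v_max) == (75.0, 125.0)

    def test_invariants_enforced(self):
        with pytest.raises(ConfigError):
            CalibrationProfile(
                body_range=HsvRange(0, 1, 0, 1, 0, 1),
                eye_range=HsvRange(0, 1, 0, 1, 0, 1),
                ax=-5, ay=150, alpha_th=100, crop=CropSpec(0, 0, 10, 10))
        with pytest.raises(ConfigError):
            HsvRange(0.5, 0.3, 0, 1, 0, 1)
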