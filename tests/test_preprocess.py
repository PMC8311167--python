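"""Loading, cropping, calibration, enhancement and binarization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octaquant import io as oio
from octaquant.errors import GeometryError, InputError, ParameterError, UsageError
from octaquant.preprocess import (
    binarize_adaptive,
    crop_scan_region,
    enhance_contrast,
    load_enface,
    remove_large_vessels,
    rescale_isotropic,
    segment_large_vessels,
)
from octaquant.types import AcquisitionMeta, BinaryVesselMap, EnFaceAngiogram, IsotropicAngiogram


def meta(**kw):
    d = dict(subject_id="S1", eye="OD", plexus="SVC", scale_x_um=1.0, scale_y_um=1.0)
    d.update(kw)
    return AcquisitionMeta(**d)


def iso(pixels, **kw):
    return IsotropicAngiogram(pixels=np.asarray(pixels), meta=meta(**kw))


class TestLoad:
    def test_checkerboard_round_trip(self, tmp_path):
        board = (np.indices((32, 32)).sum(axis=0) % 2 * 255).astype(np.uint8)
        p = tmp_path / "board.png"
        oio.write_image_png(p, board)
        img = load_enface(p, meta())
        assert img.pixels.dtype == np.uint8
        np.testing.assert_array_equal(img.pixels, board)
        img2 = load_enface(p, meta())
        np.testing.assert_array_equal(img.pixels, img2.pixels)

    def test_color_input_becomes_luminance(self, tmp_path):
        rgb = np.zeros((8, 8, 3), np.uint8)
        rgb[..., 1] = 255  # pure green
        p = tmp_path / "rgb.png"
        import imageio.v3 as iio

        iio.imwrite(p, rgb)
        img = load_enface(p, meta())
        assert img.pixels.ndim == 2
        assert np.all(img.pixels == round(0.587 * 255))

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "junk.png"
        p.write_bytes(b"not an image")
        with pytest.raises(InputError):
            load_enface(p, meta())


class TestCrop:
    def test_identity_crop(self):
        px = np.arange(64, dtype=np.uint8).reshape(8, 8)
        img = EnFaceAngiogram(px, meta(crop_box=(0, 0, 8, 8)))
        out = crop_scan_region(img)
        np.testing.assert_array_equal(out.pixels, px)

    def test_offsets_exhaustively_on_toy_image(self):
        px = np.arange(256, dtype=np.uint8).reshape(16, 16)
        x0, y0, x1, y1 = 3, 5, 11, 14
        out = crop_scan_region(EnFaceAngiogram(px, meta(crop_box=(x0, y0, x1, y1))))
        assert out.shape == (y1 - y0, x1 - x0)
        for r in range(out.shape[0]):
            for c in range(out.shape[1]):
                assert out.pixels[r, c] == px[r + y0, c + x0]

    def test_out_of_bounds_box_raises(self):
        px = np.zeros((8, 8), np.uint8)
        with pytest.raises(GeometryError):
            crop_scan_region(EnFaceAngiogram(px, meta(crop_box=(0, 0, 9, 8))))


class TestRescale:
    def test_identity_scale(self):
        px = np.arange(64, dtype=np.uint8).reshape(8, 8)
        out = rescale_isotropic(EnFaceAngiogram(px, meta()))
        np.testing.assert_array_equal(out.pixels, px)

    def test_shape_follows_device_scaling(self):
        px = np.zeros((525, 525), np.uint8)
        out = rescale_isotropic(EnFaceAngiogram(px, meta(scale_x_um=5.6, scale_y_um=5.6)))
        assert out.shape == (2940, 2940)

    def test_constant_image_stays_constant(self):
        px = np.full((40, 40), 77, np.uint8)
        out = rescale_isotropic(EnFaceAngiogram(px, meta(scale_x_um=2.5, scale_y_um=2.5)))
        assert out.shape == (100, 100)
        assert np.all(out.pixels == 77)

    def test_crop_then_rescale_commutes_with_rescale_then_crop(self, rng):
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(rng.random((64, 64)) * 200, 4)
        px = np.clip(smooth, 0, 255).astype(np.uint8)
        box = (8, 8, 40, 40)
        a = rescale_isotropic(
            crop_scan_region(EnFaceAngiogram(px, meta(scale_x_um=2, scale_y_um=2, crop_box=box)))
        )
        b_full = rescale_isotropic(EnFaceAngiogram(px, meta(scale_x_um=2, scale_y_um=2)))
        b = b_full.pixels[16:80, 16:80]
        interior = (slice(2, -2), slice(2, -2))
        assert np.abs(a.pixels[interior].astype(int) - b[interior].astype(int)).max() <= 2


class TestEnhance:
    def test_constant_image_maps_to_zero(self):
        out = enhance_contrast(iso(np.full((64, 64), 113, np.uint8)))
        assert np.all(out.pixels == 0)

    def test_thin_line_preserved_background_suppressed(self):
        px = np.full((80, 80), 20, np.uint8)
        px[40, 10:70] = 200
        out = enhance_contrast(iso(px), median_radius_um=1.0, tophat_radius_um=10.0)
        assert out.pixels[40, 20:60].mean() > 100
        assert out.pixels[10, 10:70].mean() < 5

    def test_salt_noise_removed_by_median(self):
        px = np.full((60, 60), 50, np.uint8)
        px[10, 10] = px[30, 45] = 255
        out = enhance_contrast(iso(px), median_radius_um=2.0, tophat_radius_um=10.0)
        assert out.pixels[10, 10] == out.pixels[30, 45] == 0

    def test_oversized_radius_raises(self):
        with pytest.raises(ParameterError):
            enhance_contrast(iso(np.zeros((20, 20), np.uint8)), tophat_radius_um=15.0)


class TestBinarize:
    def test_constant_image_gives_empty_mask(self):
        out = binarize_adaptive(iso(np.full((100, 100), 120, np.uint8)), 21, 2)
        assert not out.mask.any()

    def test_half_bright_half_dark(self):
        # only locally-brighter structure is foreground: the bright rim at
        # the step (where the window straddles both halves) fires, flat
        # interiors on either side do not
        px = np.zeros((100, 100), np.uint8)
        px[:, 50:] = 200
        out = binarize_adaptive(iso(px), 11, 2)
        assert out.mask[:, 50:55].all()
        assert not out.mask[:, 70:].any()
        assert not out.mask[:, :50].any()

    def test_bright_stripe_recovered(self):
        px = np.full((120, 120), 10, np.uint8)
        truth = np.zeros((120, 120), bool)
        truth[:, 55:65] = True
        px[truth] = 180
        out = binarize_adaptive(iso(px), 41, 5)
        jac = (out.mask & truth).sum() / (out.mask | truth).sum()
        assert jac >= 0.9

    def test_invariant_under_global_intensity_shift(self):
        rngl = np.random.default_rng(7)
        px = (rngl.random((80, 80)) * 100).astype(np.uint8)
        a = binarize_adaptive(iso(px), 21, 3)
        b = binarize_adaptive(iso(px + 50), 21, 3)
        np.testing.assert_array_equal(a.mask, b.mask)


class TestLargeVessels:
    def test_bimodal_band_threshold_matches_brute_force(self):
        px = np.full((200, 200), 30, np.uint8)
        px[:, 80:140] = 220
        out = segment_large_vessels(iso(px), caliber_floor_um=20)
        assert out.large_vessels
        assert out.mask[:, 100:120].all()
        assert not out.mask[:, :60].any()
        # brute-force between-class-variance maximizer on the 2-level histogram
        from skimage.filters import threshold_otsu

        vals = px.ravel().astype(float)
        best_t, best_v = None, -1.0
        for t in range(256):
            lo, hi = vals[vals <= t], vals[vals > t]
            if lo.size == 0 or hi.size == 0:
                continue
            v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert abs(threshold_otsu(px) - best_t) <= 1

    def test_thin_capillaries_below_caliber_floor_yield_empty_mask(self):
        px = np.full((300, 300), 20, np.uint8)
        for c in range(20, 300, 40):
            px[:, c : c + 8] = 210  # 8 um capillaries only
        out = segment_large_vessels(iso(px), caliber_floor_um=20)
        assert not out.mask.any()

    def test_flat_image_gives_empty_mask(self):
        out = segment_large_vessels(iso(np.zeros((64, 64), np.uint8)))
        assert not out.mask.any()

    def test_dvc_is_rejected(self):
        with pytest.raises(UsageError):
            segment_large_vessels(iso(np.zeros((64, 64), np.uint8), plexus="DVC"))


class TestRemoveLargeVessels:
    def _pair(self, bmask, lmask):
        m = meta()
        return (
            BinaryVesselMap(bmask, "SVC", m),
            BinaryVesselMap(lmask, "SVC", m, large_vessels=True),
        )

    def test_empty_large_mask_is_identity(self, rng):
        bm = rng.random((16, 16)) > 0.5
        b, l = self._pair(bm, np.zeros((16, 16), bool))
        out = remove_large_vessels(b, l)
        np.testing.assert_array_equal(out.mask, bm)
        assert out.microvessels_only

    def test_equal_masks_empty_output(self, rng):
        bm = rng.random((16, 16)) > 0.5
        out = remove_large_vessels(*self._pair(bm, bm))
        assert not out.mask.any()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**64 - 1))
    def test_set_identity_on_random_grids(self, seed):
        r = np.random.default_rng(seed)
        bm, lm = r.random((8, 8)) > 0.4, r.random((8, 8)) > 0.6
        out = remove_large_vessels(*self._pair(bm, lm))
        assert out.mask.sum() == bm.sum() - (bm & lm).sum()
        assert not (out.mask & ~bm).any()  # always a subset of the input

    def test_shape_mismatch_raises(self):
        b, _ = self._pair(np.ones((8, 8), bool), np.ones((8, 8), bool))
        _, l = self._pair(np.ones((9, 9), bool), np.ones((9, 9), bool))
        with pytest.raises(GeometryError):
            remove_large_vessels(b, l)
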