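"""Green-channel extraction, background estimation and shade correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from odseg import (
    InvalidInputError,
    ParameterError,
    estimate_background,
    extract_green,
    normalize,
    open_green,
    preprocess,
    shade_correct,
)
from odseg.preprocess import FundusImage


def _rgb_from_green(green_u8: np.ndarray) -> FundusImage:
    g = np.asarray(green_u8, dtype=np.uint8)
    return FundusImage(np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=-1))


class TestExtractGreen:
    def test_scales_8bit_values_to_unit_range(self):
        g = np.zeros((64, 64), dtype=np.uint8)
        g[:2, :2] = [[0, 51], [102, 255]]
        out = extract_green(_rgb_from_green(g))
        np.testing.assert_allclose(out[:2, :2], [[0.0, 0.2], [0.4, 1.0]])

    def test_zero_and_saturated_images(self):
        assert extract_green(_rgb_from_green(np.zeros((64, 64)))).max() == 0.0
        assert np.all(extract_green(_rgb_from_green(np.full((64, 64), 255))) == 1.0)

    def test_rejects_non_rgb_input(self):
        with pytest.raises(InvalidInputError):
            FundusImage(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            FundusImage(np.zeros((64, 64, 4), dtype=np.uint8))


class TestEstimateBackground:
    def test_constant_raster_is_fixed_point(self):
        out = estimate_background(np.full((20, 20), 0.37), kernel=5)
        np.testing.assert_allclose(out, 0.37)

    def test_single_impulse_mean_response(self):
        raster = np.zeros((9, 9))
        raster[4, 4] = 1.0
        out = estimate_background(raster, kernel=3)
        assert out[4, 4] == pytest.approx(1.0 / 9.0)

    def test_kernel_spanning_whole_uniform_image(self):
        out = estimate_background(np.full((9, 9), 0.5), kernel=9)
        np.testing.assert_allclose(out, 0.5)

    @pytest.mark.parametrize("kernel", [2, 1, 0, 21])
    def test_rejects_bad_kernel(self, kernel):
        with pytest.raises(ParameterError):
            estimate_background(np.zeros((10, 10)), kernel=kernel)

    def test_bounded_by_input_extrema_and_offset_equivariant(self, rng):
        raster = rng.random((30, 30))
        out = estimate_background(raster, kernel=7)
        assert out.min() >= raster.min() - 1e-12
        assert out.max() <= raster.max() + 1e-12
        shifted = estimate_background(raster + 0.3, kernel=7)
        np.testing.assert_allclose(shifted, out + 0.3)


class TestOpenGreen:
    def test_flat_image_unchanged(self):
        np.testing.assert_allclose(open_green(np.full((15, 15), 0.6), 2), 0.6)

    def test_removes_thin_bright_line(self):
        raster = np.full((21, 21), 0.1)
        raster[10, :] = 0.9
        out = open_green(raster, se_radius=2)
        np.testing.assert_allclose(out, 0.1)

    def test_anti_extensive_and_idempotent(self, rng):
        raster = rng.random((40, 40))
        once = open_green(raster, 3)
        assert np.all(once <= raster + 1e-12)
        np.testing.assert_allclose(open_green(once, 3), once, atol=1e-12)

    def test_retains_large_disc(self):
        rr, cc = np.ogrid[:41, :41]
        disc = (np.hypot(rr - 20, cc - 20) <= 9).astype(float)
        out = open_green(disc, se_radius=3)
        # Interior of a disc 3x the element radius survives.
        assert out[20, 20] == 1.0
        assert out[disc > 0].sum() >= 0.7 * disc.sum()


class TestNormalize:
    def test_self_subtraction_and_constants(self, rng):
        raster = rng.random((8, 8))
        np.testing.assert_allclose(normalize(raster, raster), 0.0)
        np.testing.assert_allclose(
            normalize(np.full((4, 4), 0.8), np.full((4, 4), 0.5)), 0.3
        )

    def test_worked_two_by_two(self):
        i_open = np.array([[0.9, 0.5], [0.2, 0.7]])
        i_bg = np.full((2, 2), 0.5)
        np.testing.assert_allclose(
            normalize(i_open, i_bg), [[0.4, 0.0], [-0.3, 0.2]]
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize(np.zeros((3, 3)), np.zeros((4, 4)))


class TestShadeCorrect:
    def test_constant_background_lands_on_half(self):
        for value in (-2.0, 0.0, 0.4, 7.0):
            i_sc, mode = shade_correct(np.full((16, 16), value))
            np.testing.assert_allclose(i_sc, 0.5)
            assert mode == pytest.approx(value)

    def test_bright_outlier_clamped_to_one(self):
        i_norm = np.zeros((16, 16))
        i_norm[3, 3] = 0.8
        i_sc, mode = shade_correct(i_norm)
        assert i_sc[3, 3] == 1.0
        # Background stays at 0.5 up to half a histogram bin.
        assert abs(i_sc[0, 0] - 0.5) <= 0.8 / 256

    def test_dark_outlier_clamped_to_zero(self):
        i_norm = np.zeros((16, 16))
        i_norm[3, 3] = -0.8
        i_sc, _ = shade_correct(i_norm)
        assert i_sc[3, 3] == 0.0
        assert abs(i_sc[0, 0] - 0.5) <= 0.8 / 256

    def test_output_always_in_unit_interval(self, rng):
        i_sc, _ = shade_correct(rng.normal(0, 5, (50, 50)))
        assert i_sc.min() >= 0.0 and i_sc.max() <= 1.0

    @given(offset=st.floats(-10, 10, allow_nan=False))
    def test_translation_invariance(self, offset):
        rng = np.random.default_rng(99)
        i_norm = rng.normal(0.0, 0.2, (24, 24))
        base, _ = shade_correct(i_norm)
        shifted, _ = shade_correct(i_norm + offset)
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_mode_of_corrected_image_is_half_within_one_bin(self, rng):
        i_norm = rng.normal(0.0, 0.1, (64, 64))
        i_sc, _ = shade_correct(i_norm)
        _, mode_after = shade_correct(i_sc)
        bin_width = (i_sc.max() - i_sc.min()) / 256
        assert abs(mode_after - 0.5) <= bin_width

    def test_empty_raster_rejected(self):
        with pytest.raises(InvalidInputError):
            shade_correct(np.zeros((0, 0)))


def test_preprocess_pipeline_shapes_and_range(clean_phantom):
    img, _, _ = clean_phantom
    pre = preprocess(img)
    shape = img.pixels.shape[:2]
    for name in ("green", "i_open", "i_bg", "i_norm", "i_sc"):
        assert getattr(pre, name).shape == shape
    assert pre.i_sc.min() >= 0.0 and pre.i_sc.max() <= 1.0
    # The phantom background is the modal region and must end up near 0.5.
    hist, edges = np.histogram(pre.i_sc, bins=256)
    mode_center = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
    assert abs(mode_center - 0.5) < 0.02
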