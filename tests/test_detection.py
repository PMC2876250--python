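"""Four-step precipitate classifier: grayscale, normalize, filter,
threshold-and-thin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from silverquant.detection import (
    LUMA_WEIGHTS,
    DetectionParams,
    PrecipitateMap,
    count_field,
    default_kernel,
    detect_field,
    filter_spots,
    normalize_median,
    thin_and_count,
    threshold_spots,
    to_grayscale,
)
from silverquant.fields import LayerLabel, MeasuringField, build_field
from silverquant.synthetic import ImageSimSpec, generate_image

from conftest import random_rect_mask
from _oracles import flood_fill_count

FIELD = build_field(LayerLabel("DG", "iML", "spb"), (0, 0))


class TestToGrayscale:
    def test_gray_rgb_maps_to_its_common_value(self):
        img = np.full((4, 5, 3), 0.37)
        np.testing.assert_allclose(to_grayscale(img), 0.37)

    def test_idempotent_on_grayscale(self):
        img = np.random.default_rng(0).random((6, 7))
        np.testing.assert_array_equal(to_grayscale(img), img)

    def test_rgb_reduces_to_weighted_sum_pixelwise(self):
        rng = np.random.default_rng(1)
        img = rng.random((5, 6, 3))
        expected = np.empty((5, 6))
        for r in range(5):
            for c in range(6):
                expected[r, c] = sum(img[r, c, k] * LUMA_WEIGHTS[k] for k in range(3))
        np.testing.assert_allclose(to_grayscale(img), expected)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4)))


class TestNormalizeMedian:
    def test_median_is_shifted_to_zero(self):
        raster = np.full((3, 3), 17.0)
        raster[0, 0] = 30
        out = normalize_median(raster)
        assert np.median(out) == 0.0

    def test_all_zero_raster_is_a_fixed_point(self):
        z = np.zeros((4, 4))
        np.testing.assert_array_equal(normalize_median(z), z)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        raster = rng.random((9, 9))
        once = normalize_median(raster)
        np.testing.assert_allclose(normalize_median(once), once)

    def test_reconstruction_against_brute_force_median(self):
        rng = np.random.default_rng(3)
        raster = rng.random((7, 11))
        flat = sorted(raster.ravel().tolist())
        n = len(flat)
        med = (flat[n // 2 - 1] + flat[n // 2]) / 2 if n % 2 == 0 else flat[n // 2]
        out = normalize_median(raster)
        np.testing.assert_allclose(out + med, raster)


class TestFilterSpots:
    def test_constant_raster_gives_zero_response(self):
        out = filter_spots(np.full((10, 10), 3.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_delta_response_matches_direct_summation(self):
        """Convolution of an isolated bright pixel, verified against an
        explicit double loop on a 7x7 toy raster."""
        raster = np.zeros((7, 7))
        raster[3, 3] = 2.0
        kernel = default_kernel()
        out = filter_spots(raster, kernel)
        kh, kw = kernel.shape
        expected = np.zeros_like(raster)
        for i in range(7):
            for j in range(7):
                acc = 0.0
                for m in range(kh):
                    for n in range(kw):
                        r, c = i - (m - kh // 2), j - (n - kw // 2)
                        if 0 <= r < 7 and 0 <= c < 7:
                            acc += kernel[m, n] * raster[r, c]
                expected[i, j] = acc
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_peak_response_at_isolated_bright_pixel(self):
        raster = np.zeros((11, 11))
        raster[5, 5] = 1.0
        out = filter_spots(raster)
        assert out.argmax() == np.ravel_multi_index((5, 5), out.shape)
        assert out[5, 5] == pytest.approx(1.0)

    def test_shift_invariance_for_identical_spots(self):
        raster = np.zeros((9, 30))
        raster[4, 6] = raster[4, 22] = 1.0
        out = filter_spots(raster)
        np.testing.assert_allclose(
            out[1:8, 3:10], out[1:8, 19:26], atol=1e-12
        )

    def test_kernel_larger_than_raster_rejected(self):
        with pytest.raises(ValueError, match="larger than raster"):
            filter_spots(np.zeros((3, 3)), np.zeros((5, 5)))

    def test_non_zero_sum_kernel_rejected_by_params(self):
        with pytest.raises(ValueError, match="sum to ~0"):
            DetectionParams(kernel=np.ones((3, 3)))


class TestThreshold:
    def test_threshold_above_max_gives_empty_mask(self):
        f = np.random.default_rng(4).random((5, 5))
        assert not threshold_spots(f, f.max() + 1).any()

    def test_threshold_below_min_gives_full_mask(self):
        f = np.random.default_rng(5).random((5, 5))
        assert threshold_spots(f, f.min() - 1).all()

    def test_mask_matches_per_pixel_comparison(self):
        f = np.random.default_rng(6).random((7, 7))
        thr = 0.4
        expected = np.array([[f[r, c] > thr for c in range(7)] for r in range(7)])
        np.testing.assert_array_equal(threshold_spots(f, thr), expected)

    @given(
        thr1=st.floats(-1, 1),
        thr2=st.floats(-1, 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_pixels(self, thr1, thr2):
        f = np.random.default_rng(7).standard_normal((6, 6))
        lo, hi = min(thr1, thr2), max(thr1, thr2)
        assert not (threshold_spots(f, hi) & ~threshold_spots(f, lo)).any()


class TestThinAndCount:
    def test_count_is_size_invariant(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1, 1] = True  # area 1
        mask[5:7, 5:7] = True  # area 4
        mask[12:15, 12:15] = True  # area 9
        assert thin_and_count(mask).count == 3

    def test_empty_mask_counts_zero(self):
        out = thin_and_count(np.zeros((5, 5), dtype=bool))
        assert out.count == 0 and not out.points.any()

    def test_representative_pixels_lie_inside_their_component(self):
        rng = np.random.default_rng(8)
        mask = random_rect_mask(rng, shape=(60, 80), n_rects=12, min_gap=2)
        out = thin_and_count(mask)
        assert out.count == 12
        assert (mask & out.points).sum() == 12  # one rep per component, inside

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        """50 random possibly-overlapping rectangles: count must equal an
        independent BFS flood fill under both connectivities."""
        mask = random_rect_mask(rng, shape=(50, 600), n_rects=50)
        assert (
            thin_and_count(mask, connectivity).count
            == flood_fill_count(mask, connectivity)
        )

    def test_diagonal_touch_distinguishes_connectivities(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert thin_and_count(mask, 8).count == 1
        assert thin_and_count(mask, 4).count == 2

    def test_count_must_match_set_pixels(self):
        with pytest.raises(ValueError):
            PrecipitateMap(points=np.ones((2, 2), dtype=bool), count=1)


class TestCountField:
    def test_recovers_ground_truth_without_noise(self):
        spec = ImageSimSpec(n_spots=250, noise_sigma=0.0, seed=1)
        img, truth = generate_image(spec)
        assert count_field(img, FIELD) == len(truth) == 250

    def test_blank_field_counts_zero(self):
        img = np.full((50, 600), 0.05)
        assert count_field(img, FIELD) == 0

    def test_deterministic(self):
        img, _ = generate_image(ImageSimSpec(n_spots=120, seed=6))
        assert count_field(img, FIELD) == count_field(img, FIELD)

    def test_component_straddling_subfield_join_counted_once(self):
        img = np.full((50, 600), 0.05)
        img[20:23, 198:203] = 0.9  # spans the join at column 200
        assert count_field(img, FIELD) == 1

    def test_intensity_shift_invariance(self):
        """Adding a constant offset to the whole image leaves counts
        unchanged (median normalization removes it)."""
        img, _ = generate_image(ImageSimSpec(n_spots=100, noise_sigma=0.0, seed=3))
        assert count_field(img, FIELD) == count_field(img + 0.08, FIELD)

    def test_size_invariance_under_dilation(self):
        """Dilating every spot without merging leaves the count unchanged."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = random_rect_mask(rng, shape=(50, 600), n_rects=40, min_gap=4)
            dilated = ndimage.binary_dilation(mask, structure=np.ones((3, 3)))
            assert thin_and_count(mask).count == thin_and_count(dilated).count == 40

    def test_detection_coordinates_land_near_true_centres(self):
        spec = ImageSimSpec(n_spots=80, noise_sigma=0.05, seed=10)
        img, truth = generate_image(spec)
        det = detect_field(img, FIELD)
        d = np.abs(
            det.coordinates[:, None, :] - truth.spot_centers[None, :, :]
        ).max(axis=2).min(axis=1)
        assert (d <= 2).all()
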