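"""Background correction against the brute-force opening oracle; projection."""

import numpy as np
import pytest

from calwave.preprocess import (
    BackgroundParams,
    apply_spectrum_lut,
    estimate_background,
    slice_sum,
    subtract_background,
)
from calwave.stack_io import ImageStack
from calwave.synth_movies import SceneConfig, generate_movie

from oracles import oracle_ball_depth, oracle_opening, oracle_paraboloid_depth


def _params(radius, method="rolling_ball"):
    return BackgroundParams(radius=radius, method=method, allow_downsample=False)


def _random_frame(rng, n=32):
    # smooth ramp + blobs + noise: typical uneven-illumination scene
    y, x = np.mgrid[0:n, 0:n]
    frame = 20 + 0.8 * x + 0.3 * y + rng.uniform(0, 5, (n, n))
    for _ in range(3):
        cy, cx = rng.uniform(4, n - 4, 2)
        r = rng.uniform(2, 4)
        d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        frame += 60 * np.clip(r - d, 0, 1)
    return frame


class TestEstimateBackground:
    @pytest.mark.parametrize("method", ["rolling_ball", "sliding_paraboloid"])
    def test_constant_frame_is_its_own_background(self, method):
        frame = np.full((20, 20), 7.5)
        bg = estimate_background(frame, _params(6, method))
        np.testing.assert_allclose(bg, 7.5)

    def test_impulse_narrower_than_ball_removed(self):
        # the ball cannot enter a 1-pixel spike; the exact cap may still
        # ride up the flank by one curvature step r - sqrt(r^2 - 1)
        r = 10.0
        frame = np.zeros((31, 31))
        frame[15, 15] = 100.0
        bg = estimate_background(frame, _params(r))
        cap_step = r - np.sqrt(r * r - 1)
        assert bg.max() <= cap_step + 1e-9
        assert bg.max() < 0.1  # spike itself (100) is entirely rejected

    @pytest.mark.parametrize("radius", [3.0, 7.5, 12.0])
    def test_matches_brute_force_ball_oracle(self, rng, radius):
        frame = _random_frame(rng)
        bg = estimate_background(frame, _params(radius))
        expected = oracle_opening(frame, oracle_ball_depth(radius))
        np.testing.assert_allclose(bg, expected, atol=1e-9)

    @pytest.mark.parametrize("radius", [3.0, 9.0])
    def test_matches_brute_force_paraboloid_oracle(self, rng, radius):
        frame = _random_frame(rng)
        bg = estimate_background(frame, _params(radius, "sliding_paraboloid"))
        span = float(frame.max() - frame.min())
        expected = oracle_opening(frame, oracle_paraboloid_depth(radius, span))
        np.testing.assert_allclose(bg, expected, atol=1e-9)

    def test_anti_extensive_idempotent_increasing(self, rng):
        frame = _random_frame(rng)
        p = _params(8)
        bg = estimate_background(frame, p)
        assert np.all(bg <= frame + 1e-9)
        np.testing.assert_allclose(estimate_background(bg, p), bg, atol=1e-9)
        bigger = frame + rng.uniform(0, 10, frame.shape)
        assert np.all(estimate_background(bigger, p) >= bg - 1e-9)

    def test_translation_equivariant_in_interior(self, rng):
        pattern = rng.uniform(0, 50, (10, 10))
        f1 = np.zeros((48, 48))
        f2 = np.zeros((48, 48))
        f1[12:22, 12:22] = pattern
        f2[15:25, 17:27] = pattern  # shifted by (+3, +5)
        p = _params(4)
        bg1 = estimate_background(f1, p)
        bg2 = estimate_background(f2, p)
        np.testing.assert_allclose(bg1[8:26, 8:26], bg2[11:29, 13:31], atol=1e-9)

    def test_downsampled_path_stays_below_frame(self, rng):
        frame = _random_frame(rng, n=96)
        bg = estimate_background(frame, BackgroundParams(radius=30))
        assert bg.shape == frame.shape
        assert np.all(bg <= frame + 1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            BackgroundParams(radius=0)
        with pytest.raises(ValueError, match="non-finite"):
            estimate_background(np.array([[1.0, np.nan]]), _params(2))


class TestSubtractBackground:
    def test_constant_stack_goes_to_zero(self):
        stack = ImageStack(np.full((4, 16, 16), 9.0), 5.0)
        out = subtract_background(stack, _params(5))
        np.testing.assert_allclose(out.frames, 0.0, atol=1e-9)
        assert out.frame_interval == 5.0

    def test_blob_on_zero_background_preserved(self):
        # background under a blob narrower than the ball is at most one
        # curvature step of the cap over the blob half-width
        r, w = 12.0, 3.0
        y, x = np.mgrid[0:32, 0:32]
        blob = 80 * np.clip(w - np.sqrt((x - 16.0) ** 2 + (y - 16.0) ** 2), 0, 1)
        stack = ImageStack(np.stack([blob, blob * 0.5]), 5.0)
        out = subtract_background(stack, _params(r))
        cap_step = r - np.sqrt(r * r - w * w)
        np.testing.assert_allclose(out.frames, stack.frames, atol=cap_step + 1e-9)

    def test_gradient_removed_within_oracle_residual_bound(self):
        # movie = cells + smooth gradient (no baseline/noise/bleach); the
        # corrected movie must match the clean one up to the residual the
        # opening leaves on the gradient alone
        config = SceneConfig(
            shape=(64, 64),
            n_cells=3,
            cell_radius_range=(3.0, 5.0),
            baseline_intensity=0.0,
            resting_intensity=25.0,
            amplitude_range=(30.0, 50.0),
            event_rate=0.01,
            n_frames=8,
            illumination_gradient=30.0,
            bleach_tau=np.inf,
            noise_sigma=0.0,
            seed=11,
        )
        stack, truth = generate_movie(config)
        params = _params(15)
        corrected = subtract_background(
            ImageStack(stack.frames.astype(float), stack.frame_interval), params
        )
        gradient = stack.frames[0].astype(float) - truth.clean_stack.frames[0]
        residual = gradient - oracle_opening(gradient, oracle_ball_depth(15))
        bound = residual.max() + 1.0  # +1 for the uint16 quantization
        diff = np.abs(corrected.frames - truth.clean_stack.frames)
        assert diff.max() <= bound


class TestSpectrumLut:
    def test_low_maps_to_red_high_to_violet(self):
        frame = np.array([[0.0, 50.0, 100.0]])
        rgb = apply_spectrum_lut(frame, low=0, high=100)
        assert tuple(rgb[0, 0]) == (255, 0, 0)  # pure red
        r, g, b = rgb[0, 2]
        assert b == 255 and g == 0 and 0 < r < 255  # violet = red-blue blend

    def test_hue_monotone_in_intensity(self):
        import colorsys

        frame = np.linspace(0, 1, 32)[None]
        rgb = apply_spectrum_lut(frame, low=0, high=1).astype(float) / 255
        hues = [colorsys.rgb_to_hsv(*rgb[0, i])[0] for i in range(32)]
        assert all(h2 >= h1 for h1, h2 in zip(hues, hues[1:]))

    def test_bad_anchors_rejected(self):
        with pytest.raises(ValueError):
            apply_spectrum_lut(np.zeros((2, 2)), low=5, high=5)


class TestSliceSum:
    def test_single_frame_identity(self, rng):
        frame = rng.integers(0, 1000, (8, 8)).astype(np.uint16)
        proj = slice_sum(ImageStack(frame[None], 1.0))
        np.testing.assert_array_equal(proj.values, frame)

    def test_zero_stack(self):
        proj = slice_sum(ImageStack(np.zeros((5, 4, 4), np.uint8), 1.0))
        assert not proj.values.any()

    def test_frame_permutation_invariant(self, rng):
        frames = rng.integers(0, 65535, (10, 6, 6)).astype(np.uint16)
        proj = slice_sum(ImageStack(frames, 1.0))
        perm = rng.permutation(10)
        proj2 = slice_sum(ImageStack(frames[perm], 1.0))
        np.testing.assert_array_equal(proj.values, proj2.values)

    def test_concatenation_additive(self, rng):
        a = rng.integers(0, 100, (4, 5, 5)).astype(np.uint16)
        b = rng.integers(0, 100, (7, 5, 5)).astype(np.uint16)
        left = slice_sum(ImageStack(np.concatenate([a, b]), 1.0)).values
        right = (
            slice_sum(ImageStack(a, 1.0)).values + slice_sum(ImageStack(b, 1.0)).values
        )
        np.testing.assert_array_equal(left, right)

    def test_no_overflow_accumulator(self):
        stack = ImageStack(np.full((3, 2, 2), 65535, np.uint16), 1.0)
        assert slice_sum(stack).values.dtype == np.int64
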