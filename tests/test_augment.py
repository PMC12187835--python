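"""Augmentation transforms: closed-form examples, determinism, clipping,
and the sampling distributions of the stochastic parameters."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from skimage.color import rgb2gray

from slnpatch.augment import (
    AugmentationConfig,
    apply_augmentations,
    channel_separate,
    compute_channel_stats,
    contrast_brightness,
    gaussian_noise,
    gray_hsv_recolor,
    salt_pepper,
    sample_plan,
)


@pytest.fixture()
def patch(rng):
    return rng.integers(0, 256, size=(90, 90, 3)).astype(np.uint8)


def constant_patch(value: int) -> np.ndarray:
    return np.full((90, 90, 3), value, dtype=np.uint8)


class TestContrastBrightness:
    @pytest.mark.parametrize(
        "alpha, beta, value, expected", [(1.0, 0.0, 100, 100), (0.0, 0.0, 100, 0), (2.0, 10.0, 100, 210)]
    )
    def test_closed_form(self, alpha, beta, value, expected):
        out = contrast_brightness(constant_patch(value), alpha, beta)
        assert (out == expected).all()

    def test_clipping_no_wraparound(self, patch):
        out = contrast_brightness(patch, 10.0, 10.0)
        assert out.dtype == np.uint8
        assert out.max() <= 255 and out.min() >= 0
        assert (out[patch > 30] == 255).all()  # saturated, not wrapped


class TestNoise:
    def test_gaussian_pure_shift(self):
        out = gaussian_noise(constant_patch(100), mean=10.0, sd=0.0, rng=np.random.default_rng(0))
        assert (out == 110).all()

    def test_salt_pepper_extremes(self, patch, rng):
        np.testing.assert_array_equal(salt_pepper(patch, 0.0, rng), patch)
        out = salt_pepper(patch, 1.0, rng)
        assert set(np.unique(out)) <= {0, 255}

    def test_salt_pepper_corruption_rate(self, patch):
        p = 0.3
        out = salt_pepper(patch, p, np.random.default_rng(5))
        corrupted = (out != patch).any(axis=2).mean()
        # binomial tolerance at n = 8100 pixels (~5 SD), minus chance collisions
        assert abs(corrupted - p) < 5 * np.sqrt(p * (1 - p) / 8100) + 0.01


class TestRecolorAndChannels:
    def test_min_saturation_is_grayscale(self, patch):
        out = gray_hsv_recolor(patch, saturation_value=1.0)
        gray = np.clip(np.rint(rgb2gray(patch) * 255.0), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out, np.repeat(gray[..., None], 3, axis=2))

    def test_constant_input_constant_output(self):
        out = gray_hsv_recolor(constant_patch(120), saturation_value=90.0)
        assert (out.reshape(-1, 3) == out.reshape(-1, 3)[0]).all()

    def test_luminance_order_preserved(self):
        tile = np.zeros((1, 2, 3), dtype=np.uint8)
        tile[0, 0] = 40
        tile[0, 1] = 200
        out = gray_hsv_recolor(tile, saturation_value=140.0)
        assert out[0, 0].max() < out[0, 1].max()

    def test_out_of_range_saturation_rejected(self, patch):
        with pytest.raises(ValueError):
            gray_hsv_recolor(patch, saturation_value=181.0)

    def test_channel_separate(self):
        pure_red = np.zeros((4, 4, 3), dtype=np.uint8)
        pure_red[..., 0] = 255
        assert (channel_separate(pure_red, "R") == 255).all()
        assert (channel_separate(pure_red, "G") == 0).all()
        with pytest.raises(ValueError):
            channel_separate(pure_red, "X")


class TestPipeline:
    def test_all_disabled_is_identity(self, patch):
        config = AugmentationConfig(
            enable_recolor=False,
            enable_gaussian_noise=False,
            enable_salt_pepper=False,
            enable_channel_separate=False,
            enable_contrast_brightness=False,
        )
        np.testing.assert_array_equal(apply_augmentations(patch, config, 7), patch)

    def test_same_seed_identical_output(self, patch):
        config = AugmentationConfig()
        a = apply_augmentations(patch, config, 42)
        b = apply_augmentations(patch, config, 42)
        np.testing.assert_array_equal(a, b)

    def test_output_always_uint8_in_range(self, patch):
        config = AugmentationConfig(per_transform_apply_prob=1.0)
        for seed in range(20):
            out = apply_augmentations(patch, config, seed)
            assert out.dtype == np.uint8 and out.shape == patch.shape

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            apply_augmentations(np.zeros((90, 90)), AugmentationConfig(), 0)

    def test_sampled_parameters_in_range_and_uniform(self):
        config = AugmentationConfig()
        rng = np.random.default_rng(99)
        draws = {"saturation": [], "mean": [], "p": [], "alpha": [], "beta": []}
        for _ in range(10_000):
            plan = sample_plan(config, rng)
            draws["saturation"].append(plan["recolor"]["saturation"])
            draws["mean"].append(plan["gaussian"]["mean"])
            draws["p"].append(plan["salt_pepper"]["p"])
            draws["alpha"].append(plan["contrast"]["alpha"])
            draws["beta"].append(plan["contrast"]["beta"])
        ranges = {
            "saturation": (1.0, 180.0),
            "mean": (0.0, 10.0),
            "p": (0.0, 1.0),
            "alpha": (0.0, 10.0),
            "beta": (0.0, 10.0),
        }
        for name, values in draws.items():
            lo, hi = ranges[name]
            values = np.asarray(values)
            assert values.min() >= lo and values.max() <= hi
            pvalue = stats.kstest(values, stats.uniform(loc=lo, scale=hi - lo).cdf).pvalue
            assert pvalue > 0.01, name


class TestChannelStats:
    def test_pure_tiles(self):
        white = np.full((1, 90, 90, 3), 255, dtype=np.uint8)
        cs = compute_channel_stats(white)
        assert cs.mean == (1.0, 1.0, 1.0) and cs.sd == (0.0, 0.0, 0.0)
        black = np.zeros((1, 90, 90, 3), dtype=np.uint8)
        cs = compute_channel_stats(black)
        assert cs.mean == (0.0, 0.0, 0.0)

    def test_two_point_mixture_moments(self):
        tiles = np.concatenate(
            [np.zeros((2, 90, 90, 3), dtype=np.uint8), np.full((2, 90, 90, 3), 255, np.uint8)]
        )
        cs = compute_channel_stats(tiles)
        assert cs.mean == pytest.approx((0.5, 0.5, 0.5))
        assert cs.sd == pytest.approx((0.5, 0.5, 0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_channel_stats(np.zeros((0, 90, 90, 3), dtype=np.uint8))
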