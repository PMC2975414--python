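import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from follikel.bilateral import (
    BilateralParams,
    bilateral_weights,
    filter_conventional,
    filter_gaussian,
    filter_iterative,
    filter_normalized,
)
from follikel.metrics import nmse
from follikel.phantom import (
    PhantomSpec,
    Shape,
    SpeckleParams,
    apply_speckle,
    generate_phantom,
)


def brute_force_bilateral(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Exhaustive per-pixel double loop; the reference the filters must match."""
    h = params.half_width
    H, W = img.shape
    pad = np.pad(img, h, mode="reflect")
    out = np.empty_like(img)
    for i in range(H):
        for j in range(W):
            num = den = 0.0
            jx = img[i, j]
            for dy in range(-h, h + 1):
                for dx in range(-h, h + 1):
                    jy = pad[i + h + dy, j + h + dx]
                    d = abs(jy - jx)
                    if params.mode == "normalized":
                        d /= max(abs(jx), params.epsilon)
                    w = math.exp(-(dy * dy + dx * dx) / (2 * params.sigma_d**2))
                    w *= math.exp(-(d * d) / (2 * params.sigma_r**2))
                    num += w * jy
                    den += w
            out[i, j] = num / den
    return out


class TestBilateralWeights:
    def test_constant_patch_reduces_to_spatial_gaussian(self):
        p = BilateralParams(sigma_d=1.0, sigma_r=0.3, half_width=1, mode="conventional")
        w = bilateral_weights(np.full((3, 3), 0.4), 0.4, p)
        dy, dx = np.mgrid[-1:2, -1:2]
        expected = np.exp(-(dy**2 + dx**2) / 2.0)
        assert np.allclose(w, expected, atol=1e-15)

    def test_conventional_range_factor_hand_computed(self):
        patch = np.full((3, 3), 0.5)
        patch[0, 1] = 0.6
        p = BilateralParams(sigma_d=1.0, sigma_r=0.3, half_width=1, mode="conventional")
        w = bilateral_weights(patch, 0.5, p)
        spatial = math.exp(-1.0 / 2.0)  # offset (-1, 0)
        expected = spatial * math.exp(-(0.1**2) / (2 * 0.3**2))
        assert w[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_normalized_range_factor_smaller_for_subunit_center(self):
        patch = np.full((3, 3), 0.5)
        patch[0, 1] = 0.6
        conv = BilateralParams(sigma_d=1.0, sigma_r=0.3, half_width=1, mode="conventional")
        norm = BilateralParams(sigma_d=1.0, sigma_r=0.3, half_width=1, mode="normalized")
        w_conv = bilateral_weights(patch, 0.5, conv)
        w_norm = bilateral_weights(patch, 0.5, norm)
        spatial = math.exp(-0.5)
        expected = spatial * math.exp(-((0.1 / 0.5) ** 2) / (2 * 0.3**2))
        assert w_norm[0, 1] == pytest.approx(expected, rel=1e-12)
        assert w_norm[0, 1] < w_conv[0, 1]

    def test_weights_sum_positive_center_is_max(self, rng):
        patch = rng.uniform(size=(5, 5))
        p = BilateralParams(sigma_d=1.5, sigma_r=0.2, half_width=2, mode="normalized")
        w = bilateral_weights(patch, patch[2, 2], p)
        assert w.sum() > 0
        assert w[2, 2] == w.max()

    def test_center_mismatch_rejected(self):
        p = BilateralParams(half_width=1)
        with pytest.raises(ValueError, match="central"):
            bilateral_weights(np.zeros((3, 3)), 0.5, p)


@pytest.mark.parametrize("mode", ["conventional", "normalized"])
class TestSinglePassFilters:
    def test_constant_image_fixed_point(self, mode):
        img = np.full((16, 16), 0.3)
        p = BilateralParams(sigma_d=2.0, sigma_r=0.4, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        assert np.allclose(fn(img, p), img, atol=1e-14)

    def test_matches_bruteforce_oracle(self, mode, rng):
        img = rng.uniform(size=(12, 12))
        p = BilateralParams(sigma_d=1.5, sigma_r=0.25, half_width=3, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        assert np.abs(fn(img, p) - brute_force_bilateral(img, p)).max() < 1e-12

    def test_output_within_input_range(self, mode, rng):
        img = rng.uniform(0.1, 0.9, size=(20, 20))
        p = BilateralParams(sigma_d=2.0, sigma_r=0.3, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        out = fn(img, p)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_transpose_symmetry(self, mode, rng):
        img = rng.uniform(size=(14, 18))
        p = BilateralParams(sigma_d=2.0, sigma_r=0.3, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        assert np.allclose(fn(img.T, p), fn(img, p).T, atol=1e-13)

    def test_flip_symmetry(self, mode, rng):
        img = rng.uniform(size=(15, 15))
        p = BilateralParams(sigma_d=1.5, sigma_r=0.4, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        assert np.allclose(fn(img[::-1, :], p), fn(img, p)[::-1, :], atol=1e-13)

    def test_small_sigma_r_approaches_identity(self, mode, rng):
        img = rng.uniform(0.2, 0.9, size=(12, 12))
        p = BilateralParams(sigma_d=2.0, sigma_r=1e-4, mode=mode)
        fn = filter_conventional if mode == "conventional" else filter_normalized
        assert np.abs(fn(img, p) - img).max() < 1e-3


class TestConventionalLimits:
    def test_sigma_r_infinity_equals_gaussian_smoothing(self, rng):
        img = rng.uniform(size=(24, 24))
        p = BilateralParams(sigma_d=2.0, sigma_r=1e9, mode="conventional")
        out = filter_conventional(img, p)
        ref = gaussian_filter(img, 2.0, mode="mirror", truncate=p.half_width / 2.0)
        assert np.abs(out - ref).max() < 1e-6


class TestNormalizedScaleInvariance:
    def test_output_scales_exactly_with_input(self, rng):
        # all pixels bounded away from zero so the epsilon guard is inactive
        img = rng.uniform(0.5, 1.0, size=(12, 12))
        p = BilateralParams(
            sigma_d=1.5, sigma_r=0.3, mode="normalized", epsilon=1e-12
        )
        s = 0.5
        assert np.allclose(
            filter_normalized(img * s, p), s * filter_normalized(img, p), atol=1e-12
        )

    def test_conventional_not_scale_invariant(self, rng):
        img = rng.uniform(0.5, 1.0, size=(12, 12))
        p = BilateralParams(sigma_d=1.5, sigma_r=0.3, mode="conventional")
        s = 0.5
        assert not np.allclose(
            filter_conventional(img * s, p), s * filter_conventional(img, p), atol=1e-6
        )


class TestIterativeScheme:
    def test_one_iteration_equals_single_pass(self, rng):
        img = rng.uniform(size=(16, 16))
        p = BilateralParams(sigma_d=2.0, sigma_r=0.3, mode="normalized", iterations=1)
        assert np.array_equal(filter_iterative(img, p), filter_normalized(img, p))

    def test_constant_image_any_iterations(self):
        img = np.full((12, 12), 0.6)
        p = BilateralParams(sigma_d=2.0, sigma_r=0.3, mode="normalized", iterations=4)
        assert np.allclose(filter_iterative(img, p), img, atol=1e-13)

    def test_snapshots_chain_consistently(self, rng):
        img = rng.uniform(size=(12, 12))
        p = BilateralParams(sigma_d=1.5, sigma_r=0.3, mode="conventional", iterations=3)
        out, snaps = filter_iterative(img, p, return_snapshots=True)
        assert len(snaps) == 3
        assert np.array_equal(out, snaps[-1])
        one = BilateralParams(sigma_d=1.5, sigma_r=0.3, mode="conventional", iterations=1)
        assert np.array_equal(snaps[1], filter_iterative(snaps[0], one))

    def test_five_iterations_beat_one_when_single_pass_undersmooths(
        self, packaged_clean, packaged_noisy
    ):
        # at a range parameter below the optimum one pass leaves residual
        # speckle; repeated passes keep improving the error
        p1 = BilateralParams(sigma_d=3.0, sigma_r=0.3, mode="normalized", iterations=1)
        p5 = BilateralParams(sigma_d=3.0, sigma_r=0.3, mode="normalized", iterations=5)
        nmse1 = nmse(packaged_clean, filter_iterative(packaged_noisy, p1))
        nmse5 = nmse(packaged_clean, filter_iterative(packaged_noisy, p5))
        assert nmse5 < nmse1


class TestTwoRegionRelativeResiduals:
    def test_normalized_filter_equalizes_relative_residuals(self):
        """Bright and dark homogeneous regions carry identical *relative*
        noise; the normalized filter should leave comparable relative
        residuals in both, while the conventional filter leaves more in
        the bright region."""
        spec = PhantomSpec(
            (64, 64), 0.2, (Shape("rectangle", (0.0, 32.0), (64.0, 32.0), 0.8),)
        )
        clean = generate_phantom(spec)
        dark = np.s_[5:59, 5:27]
        bright = np.s_[5:59, 37:59]
        ratios_norm, ratios_conv = [], []
        for seed in range(10):
            noisy = apply_speckle(clean, SpeckleParams(seed=seed))
            fn = filter_normalized(
                noisy, BilateralParams(sigma_d=3.0, sigma_r=0.5, mode="normalized")
            )
            fc = filter_conventional(
                noisy, BilateralParams(sigma_d=3.0, sigma_r=0.5, mode="conventional")
            )
            rel = lambda f, sl, m: (f[sl] - clean[sl]).std() / m  # noqa: E731
            ratios_norm.append(rel(fn, bright, 0.8) / rel(fn, dark, 0.2))
            ratios_conv.append(rel(fc, bright, 0.8) / rel(fc, dark, 0.2))
        assert abs(np.mean(ratios_norm) - 1.0) < 0.2
        assert np.mean(ratios_conv) > np.mean(ratios_norm) + 0.2

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BilateralParams(sigma_d=-1.0)
        with pytest.raises(ValueError):
            BilateralParams(sigma_r=0.0)
        with pytest.raises(ValueError):
            BilateralParams(iterations=0)
        with pytest.raises(ValueError):
            BilateralParams(mode="bogus")


def test_gaussian_baseline_window_truncation(rng):
    img = rng.uniform(size=(32, 32))
    out = filter_gaussian(img, sigma=3.0, window=9)
    ref = gaussian_filter(img, 3.0, mode="mirror", truncate=4 / 3.0)
    assert np.allclose(out, ref, atol=1e-14)
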