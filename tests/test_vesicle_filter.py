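"""DoG kernel construction, filtering, and thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import convolve2d

from vesicoloc import DOGParams, auto_threshold, build_dog_kernel, dog_filter, global_threshold
from vesicoloc.errors import DegenerateInputError, ParameterError, ValidationError


class TestKernel:
    def test_invalid_sigma_order_rejected(self):
        with pytest.raises(ParameterError):
            DOGParams(sigma_small_nm=300, sigma_large_nm=150)
        with pytest.raises(ParameterError):
            DOGParams(sigma_small_nm=200, sigma_large_nm=200)

    @pytest.mark.parametrize("pixel_size_nm", [40, 65, 100, 150, 200])
    def test_zero_sum_across_calibrations(self, pixel_size_nm):
        kernel = build_dog_kernel(DOGParams(), pixel_size_nm)
        assert abs(kernel.sum()) < 1e-10

    def test_identical_sigmas_cancel(self):
        # bypass the band-pass invariant: build both Gaussians directly
        from vesicoloc.vesicle_filter import _discrete_gaussian

        g = _discrete_gaussian(2.0, 8) - _discrete_gaussian(2.0, 8)
        assert np.allclose(g, 0.0)

    def test_center_positive_negative_annulus(self):
        """Pointwise-evaluated discrete Gaussians predict the kernel's sign
        structure: positive center, negative ring around 2-3 small sigmas."""
        params = DOGParams()  # 150 / 300 nm
        px = 100.0
        kernel = build_dog_kernel(params, px)
        c = kernel.shape[0] // 2
        assert kernel[c, c] > 0
        # independent pointwise oracle on the same support
        radius = c
        coords = np.arange(-radius, radius + 1, dtype=float)
        yy, xx = np.meshgrid(coords, coords, indexing="ij")

        def unit_gauss(sigma_px):
            g = np.exp(-0.5 * (yy**2 + xx**2) / sigma_px**2)
            return g / g.sum()

        oracle = unit_gauss(1.5) - unit_gauss(3.0)
        np.testing.assert_allclose(kernel, oracle, atol=1e-15)
        # annulus near 2-3 sigma_small (3-4.5 px) is negative
        r = np.sqrt(yy**2 + xx**2)
        assert (kernel[(r > 3) & (r < 4.5)] < 0).all()

    def test_extent_follows_truncation_radius(self):
        kernel = build_dog_kernel(DOGParams(truncation_radius_sigmas=3.0), 100.0)
        assert kernel.shape == (2 * int(np.ceil(3.0 * 3.0)) + 1,) * 2


class TestDogFilter:
    def test_flat_image_filters_to_nothing(self):
        for level in (1.0, 100.0, 1e4):
            out = dog_filter(np.full((32, 32), level), DOGParams(), 100.0)
            assert np.max(np.abs(out)) < 1e-9 * level

    def test_point_source_response_matches_dense_convolution(self):
        """Single bright pixel: response equals intensity x kernel, maximal
        at the source (dense scipy convolution as independent oracle)."""
        plane = np.zeros((41, 41))
        plane[20, 20] = 7.0
        params = DOGParams()
        out = dog_filter(plane, params, 100.0)
        kernel = build_dog_kernel(params, 100.0)
        assert out[20, 20] == pytest.approx(7.0 * kernel[kernel.shape[0] // 2] [kernel.shape[1] // 2], rel=1e-9)
        assert np.unravel_index(np.argmax(out), out.shape) == (20, 20)
        oracle = convolve2d(plane, kernel, mode="same", boundary="symm")
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_linearity_for_separated_sources(self):
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        a[16, 16] = 3.0
        b[48, 48] = 5.0
        params = DOGParams()
        out_sum = dog_filter(a + b, params, 100.0)
        np.testing.assert_allclose(
            out_sum, dog_filter(a, params, 100.0) + dog_filter(b, params, 100.0),
            atol=1e-9,
        )

    def test_shift_equivariance_away_from_boundary(self):
        rng = np.random.default_rng(0)
        plane = np.zeros((80, 80))
        plane[30:40, 30:40] = rng.uniform(0, 10, (10, 10))
        params = DOGParams()
        out = dog_filter(plane, params, 100.0)
        shifted = dog_filter(np.roll(plane, (5, 3), axis=(0, 1)), params, 100.0)
        np.testing.assert_allclose(
            np.roll(out, (5, 3), axis=(0, 1))[20:60, 20:60], shifted[20:60, 20:60],
            atol=1e-9,
        )

    def test_non_finite_input_rejected(self):
        plane = np.zeros((8, 8))
        plane[0, 0] = np.inf
        with pytest.raises(ValidationError):
            dog_filter(plane, DOGParams(), 100.0)


class TestThresholding:
    def test_elementwise_comparison(self):
        mask = global_threshold(np.array([[-1, 0.5], [2, 0]]), 0.0)
        np.testing.assert_array_equal(mask.values, [[0, 1], [1, 0]])
        assert mask.threshold_used == 0.0

    def test_extreme_thresholds(self):
        filtered = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert global_threshold(filtered, 5.0).n_on == 0
        assert global_threshold(filtered, 0.0).n_on == 4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        t1=st.floats(-2, 2),
        t2=st.floats(-2, 2),
    )
    def test_monotone_in_threshold(self, seed, t1, t2):
        """Raising the threshold never adds mask pixels."""
        filtered = np.random.default_rng(seed).normal(size=(12, 12))
        lo, hi = min(t1, t2), max(t1, t2)
        m_lo = global_threshold(filtered, lo).values
        m_hi = global_threshold(filtered, hi).values
        assert np.all(m_hi <= m_lo)

    def test_otsu_positive_separates_bimodal(self):
        """Otsu on strictly positive values lands between the modes; checked
        against an exhaustive scan of the between-class criterion."""
        rng = np.random.default_rng(1)
        filtered = np.concatenate(
            [rng.normal(0.1, 0.01, 400), rng.normal(10.0, 0.5, 100), [-1.0] * 100]
        ).reshape(25, 24)
        thr = auto_threshold(filtered, "otsu-positive")
        assert 0.1 < thr < 10.0
        # exhaustive oracle: maximize between-class variance over candidates
        pos = np.sort(filtered[filtered > 0])
        candidates = (pos[:-1] + pos[1:]) / 2
        best, best_score = None, -np.inf
        for c in candidates:
            lo, hi = pos[pos <= c], pos[pos > c]
            if len(lo) == 0 or len(hi) == 0:
                continue
            w0, w1 = len(lo) / len(pos), len(hi) / len(pos)
            score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if score > best_score:
                best, best_score = c, score
        # both split the two modes identically (same partition of values)
        assert (pos > thr).sum() == (pos > best).sum() == 100

    def test_quantile_extremes(self):
        filtered = np.arange(16.0).reshape(4, 4)
        assert auto_threshold(filtered, "quantile", q=1.0) == 15.0
        assert auto_threshold(filtered, "quantile", q=0.0) == 0.0

    def test_no_positive_values_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            auto_threshold(-np.ones((4, 4)), "otsu-positive")

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            auto_threshold(np.ones((4, 4)), "triangle")
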