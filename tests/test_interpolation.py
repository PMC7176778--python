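"""View interpolation: baselines, objective, estimator, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from radialfill import (EstimatorConfig, Sinogram, estimate_displacement,
                        linear_view_interp, make_phantom, objective_F,
                        regularizer_R, sinc_view_interp, sinogram_from_phantom,
                        synthesize_views, undersample_views, upsample_sinogram)


def _sino(values, coverage=360.0):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    return Sinogram(values, np.arange(n) * coverage / n, coverage,
                    coverage / n)


class TestLinearViewInterp:
    def test_factor_two_inserts_midpoints(self):
        s = _sino(np.array([[1.0, 3.0]]))
        out = linear_view_interp(s, 2)
        # views: measured 1, mid 2, measured 3, wrap-mid 2
        np.testing.assert_allclose(out.values[0], [1, 2, 3, 2])
        assert out.delta_gamma_deg == pytest.approx(s.delta_gamma_deg / 2)

    def test_factor_three_convex_weights(self):
        s = _sino(np.array([[0.0, 3.0]]))
        out = linear_view_interp(s, 3)
        np.testing.assert_allclose(out.values[0], [0, 1, 2, 3, 2, 1])

    def test_identical_views_stay_identical(self, rng):
        col = rng.random(16)
        s = _sino(np.tile(col[:, None], (1, 6)))
        out = linear_view_interp(s, 4)
        np.testing.assert_allclose(
            out.values, np.tile(col[:, None], (1, out.n_views)))

    def test_factor_below_two_rejected(self, random_sinogram):
        with pytest.raises(ValueError, match="factor"):
            linear_view_interp(random_sinogram, 1)


class TestSincViewInterp:
    def test_constant_along_views_stays_constant(self, rng):
        col = rng.random(8)
        s = _sino(np.tile(col[:, None], (1, 6)))
        out = sinc_view_interp(s, 3)
        np.testing.assert_allclose(
            out.values, np.tile(col[:, None], (1, out.n_views)), atol=1e-9)

    def test_single_harmonic_reproduced_exactly(self):
        M, factor, q = 12, 3, 4
        m = np.arange(M)
        s = _sino(np.tile(np.cos(2 * np.pi * q * m / M), (5, 1)))
        out = sinc_view_interp(s, factor)
        mm = np.arange(M * factor)
        expected = np.cos(2 * np.pi * q * mm / (M * factor))
        np.testing.assert_allclose(out.values,
                                   np.tile(expected, (5, 1)), atol=1e-9)

    def test_measured_views_preserved(self, random_sinogram):
        out = sinc_view_interp(random_sinogram, 3)
        np.testing.assert_allclose(out.values[:, ::3], random_sinogram.values,
                                   atol=1e-9)

    def test_halfturn_coverage_measured_views_preserved(self, rng):
        v = np.zeros((16, 8))
        v[2:14] = rng.random((12, 8))  # zero at the unpaired edge sample
        s = _sino(v, coverage=180.0)
        out = sinc_view_interp(s, 2)
        np.testing.assert_allclose(out.values[:, ::2], v, atol=1e-9)


class TestObjective:
    @pytest.mark.parametrize("p1,p2,n,u,expected", [
        ([0, 1, 2], [0, 1, 2], 1, 0, 0.0),   # both slopes positive
        ([0, 1], [1, 0], 1, 0, 4.0),         # +1 vs -1 slopes
        ([1, 1], [0, 1], 1, 0, 1.0),         # zero vs positive slope
    ])
    def test_regularizer_values(self, p1, p2, n, u, expected):
        assert regularizer_R(np.array(p1, float), np.array(p2, float),
                             n, u) == expected

    def test_regularizer_zero_at_left_edge(self):
        assert regularizer_R(np.array([5.0, 0.0]), np.array([1.0, 2.0]),
                             0, 0) == 0.0

    @pytest.mark.parametrize("p1,p2,n,u,lam,expected", [
        ([1.0, 2.0], [1.0, 2.0], 1, 0, 0.001, 0.0),
        ([0.0, 1.0], [0.0, 2.0], 1, 0, 0.001, 1.0),
        ([1.0, 0.0], [0.0, 1.0], 1, 0, 0.001, 1.004),
    ])
    def test_objective_hand_values(self, p1, p2, n, u, lam, expected):
        F = objective_F(np.array(p1), np.array(p2), n, u, lam)
        assert F == pytest.approx(expected, abs=1e-12)


def naive_best_u(p1, p2, n, bound_N, lam):
    """Independent exhaustive oracle: scan u = -N..N with a plain loop."""
    best_u, best_F = None, np.inf
    for u in range(-bound_N, bound_N + 1):
        F = objective_F(p1, p2, n, u, lam)
        if F < best_F:
            best_u, best_F = u, F
    return best_u, best_F


class TestEstimateDisplacement:
    def test_identical_views_give_zero_field(self, rng):
        p = rng.random(24)
        field = estimate_displacement(p, p, EstimatorConfig())
        assert np.all(field.u == 0)

    def test_shifted_bump_recovered_with_negative_shift(self):
        # p2 is p1 shifted right by 2 samples, so p2(n) = p1(n - 2)
        L = 48
        n = np.arange(L)
        p1 = np.maximum(0.0, 6.0 - np.abs(n - 20))  # triangle bump
        p2 = np.maximum(0.0, 6.0 - np.abs(n - 22))
        field = estimate_displacement(p1, p2, EstimatorConfig(bound_N=12))
        overlap = (p2 > 0) & (np.abs(n - 22) <= 4)  # strict interior
        assert np.all(field.u[overlap] == -2)

    def test_bound_holds_when_true_shift_exceeds_it(self, rng):
        L = 64
        n = np.arange(L)
        p1 = np.exp(-0.5 * ((n - 20) / 3.0) ** 2)
        p2 = np.exp(-0.5 * ((n - 40) / 3.0) ** 2)  # shift 20 > N
        field = estimate_displacement(p1, p2, EstimatorConfig(bound_N=12))
        assert np.abs(field.u).max() <= 12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            estimate_displacement(np.zeros(4), np.zeros(5))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(p1=arrays(float, 8, elements=st.floats(0, 1)),
           p2=arrays(float, 8, elements=st.floats(0, 1)))
    def test_exhaustive_optimality_property(self, p1, p2):
        cfg = EstimatorConfig(bound_N=3, lambda_reg=0.001, normalize=False)
        field = estimate_displacement(p1, p2, cfg)
        for n in range(8):
            _, best_F = naive_best_u(p1, p2, n, 3, 0.001)
            F = objective_F(p1, p2, n, int(field.u[n]), 0.001)
            assert F == best_F


class TestSynthesizeViews:
    def test_zero_displacement_reproduces_input(self, rng):
        from radialfill import DisplacementField
        p1 = rng.random(16)
        field = DisplacementField(u=np.zeros(16, int), bound_N=12, pair=(0, 1))
        for view in synthesize_views(p1, field, 4):
            np.testing.assert_array_equal(view, p1)

    def test_midpoint_uses_half_displacement_with_zero_fill(self):
        from radialfill import DisplacementField
        p1 = np.array([0.0, 4.0, 8.0])
        field = DisplacementField(u=np.ones(3, int), bound_N=2, pair=(0, 1))
        views = synthesize_views(p1, field, 2)
        np.testing.assert_array_equal(views[0], p1)
        np.testing.assert_allclose(views[1], [2.0, 6.0, 4.0])

    def test_fraction_zero_is_exact_even_for_large_u(self, rng):
        from radialfill import DisplacementField
        p1 = rng.random(10)
        field = DisplacementField(u=rng.integers(-5, 6, 10), bound_N=5,
                                  pair=(0, 1))
        np.testing.assert_array_equal(synthesize_views(p1, field, 3)[0], p1)


class TestUpsampleSinogram:
    @pytest.mark.parametrize("n_meas,factor,coverage", [
        (60, 3, 360.0), (24, 3, 180.0),
    ])
    def test_view_count_and_measured_preservation(self, features_phantom,
                                                  n_meas, factor, coverage):
        s = sinogram_from_phantom(features_phantom, n_meas, coverage, 65)
        out = upsample_sinogram(s, factor)
        assert out.n_views == n_meas * factor
        np.testing.assert_array_equal(out.values[:, ::factor], s.values)
        assert out.delta_gamma_deg == pytest.approx(s.delta_gamma_deg / factor)

    def test_disk_sinogram_propagates_unchanged(self, disk_sinogram_small):
        out = upsample_sinogram(disk_sinogram_small, 3)
        np.testing.assert_allclose(
            out.values,
            np.tile(disk_sinogram_small.values[:, :1], (1, out.n_views)),
            atol=1e-12)

    def test_complex_input_rejected(self):
        s = _sino(np.zeros((4, 4)))
        s = s.with_values(s.values.astype(complex))
        with pytest.raises(ValueError, match="magnitude"):
            upsample_sinogram(s, 2)
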