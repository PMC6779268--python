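import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fraccum.moments import (
    CumulantMap,
    DegenerateSeriesError,
    MomentGrid,
    complex_power,
    default_grid,
    fractional_cumulants,
    fractional_moments,
    normalize_series,
)

finite_series = arrays(
    np.float64,
    st.integers(min_value=5, max_value=40),
    elements=st.floats(-50, 50, allow_nan=False),
).filter(lambda a: a.std() > 1e-6)


class TestGrid:
    def test_default_spans_zero_to_five_step_tenth(self):
        g = default_grid()
        assert g.k_values[0] == 0.0
        assert g.k_values[-1] == 5.0
        assert len(g) == 51
        assert np.allclose(np.diff(g.k_values), 0.1)

    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            MomentGrid(np.array([0.0, 0.2, 0.1]))

    def test_rejects_negative_orders(self):
        with pytest.raises(ValueError):
            MomentGrid(np.array([-0.5, 0.5]))


class TestNormalize:
    def test_three_point_series_exact(self):
        # population SD of [1,2,3] is sqrt(2/3), so ends map to +-sqrt(3/2)
        out = normalize_series(np.array([1.0, 2.0, 3.0]))
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = normalize_series(rng.normal(size=100))
        np.testing.assert_allclose(normalize_series(x), x, atol=1e-12)

    @given(finite_series)
    @settings(max_examples=50, deadline=None)
    def test_output_mean_zero_var_one(self, arr):
        out = normalize_series(arr)
        assert abs(out.mean()) < 1e-10
        assert abs(out.var() - 1.0) < 1e-9

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            normalize_series(np.full(10, 3.0))


class TestComplexPower:
    def test_principal_branch_sqrt_of_minus_one(self):
        assert complex_power(-1.0, 0.5) == pytest.approx(1j, abs=1e-12)

    def test_integer_power_recovers_real(self):
        assert complex_power(-2.0, 2.0) == pytest.approx(4.0 + 0j, abs=1e-12)

    def test_polar_form_fractional(self):
        expected = 2.0 * np.sqrt(2.0) * np.exp(1.5j * np.pi)
        assert complex_power(-2.0, 1.5) == pytest.approx(expected, abs=1e-12)

    def test_zero_to_the_zero_is_one(self):
        assert complex_power(0.0, 0.0) == 1.0 + 0j
        assert complex_power(0.0, 1.3) == 0.0 + 0j

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            complex_power(2.0, -1.0)

    @given(st.floats(0.0, 5.0), st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_matches_scalar_polar_oracle(self, k, x):
        got = complex_power(x, k)
        if x >= 0:
            expected = complex(x**k)
        else:
            expected = abs(x) ** k * np.exp(1j * np.pi * k)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestMomentCurve:
    def test_boundary_conditions(self):
        rng = np.random.default_rng(7)
        x = normalize_series(rng.normal(size=500))
        curve = fractional_moments(x)
        assert curve.at(0.0) == pytest.approx(1.0 + 0j, abs=1e-12)
        assert curve.at(1.0) == pytest.approx(0.0 + 0j, abs=1e-10)
        assert curve.at(2.0) == pytest.approx(1.0 + 0j, abs=1e-10)

    def test_real_axis_crossings_at_integer_orders(self):
        rng = np.random.default_rng(8)
        x = normalize_series(rng.normal(size=2000))
        curve = fractional_moments(x)
        for k in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0):
            assert abs(curve.at(k).imag) < 1e-8

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            fractional_moments(np.array([1.0, 2.0, 5.0, 9.0]))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(9)
        x = normalize_series(rng.normal(size=30))
        grid = default_grid()
        curve = fractional_moments(x, grid)
        for a, k in enumerate(grid.k_values):
            expected = np.mean([complex_power(xi, k) for xi in x])
            assert curve.values[a] == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestCumulants:
    def test_identical_series_vanish(self):
        rng = np.random.default_rng(10)
        x = normalize_series(rng.normal(size=80))
        cmap = fractional_cumulants(x, x)
        # matmul summation order leaves ~1e-14 residue; the integrand is zero
        assert np.abs(cmap.values).max() < 1e-12

    def test_swap_negates(self):
        rng = np.random.default_rng(11)
        x = normalize_series(rng.normal(size=80))
        y = normalize_series(rng.normal(size=80))
        forward = fractional_cumulants(x, y)
        backward = fractional_cumulants(y, x)
        np.testing.assert_allclose(forward.values, -backward.values, atol=1e-12)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(12)
        x = normalize_series(rng.normal(size=60))
        y = normalize_series(rng.normal(size=60))
        cmap = fractional_cumulants(x, y)
        np.testing.assert_array_equal(cmap.values, -cmap.values.T)
        assert np.abs(np.diag(cmap.values)).max() == 0.0

    def test_two_sample_hand_evaluation(self):
        # x = [-1, 1], y = [-1, 0] normalized, then Eq.-by-hand at k=2, l=1
        x = normalize_series(np.array([-1.0, 1.0]))
        y = normalize_series(np.array([-1.0, 0.0]))
        cmap = fractional_cumulants(x, y)
        k, l = 2.0, 1.0
        expected = np.mean(
            [
                complex_power(x[i], k) * complex_power(y[i], l)
                - complex_power(x[i], l) * complex_power(y[i], k)
                for i in range(2)
            ]
        )
        assert cmap.at(k, l) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        x = normalize_series(rng.normal(size=50))
        y = normalize_series(rng.normal(size=60))
        with pytest.raises(ValueError, match="mismatch"):
            fractional_cumulants(x, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_equals_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        x = normalize_series(rng.normal(size=n))
        y = normalize_series(rng.normal(size=n))
        grid = MomentGrid(np.array([0.0, 0.3, 1.0, 1.7, 2.0, 3.3]))
        cmap = fractional_cumulants(x, y, grid)
        for a, k in enumerate(grid.k_values):
            for b, l in enumerate(grid.k_values):
                expected = np.mean(
                    [
                        complex_power(x[i], k) * complex_power(y[i], l)
                        - complex_power(x[i], l) * complex_power(y[i], k)
                        for i in range(n)
                    ]
                )
                got = cmap.values[a, b]
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_components_expose_real_imag(self):
        rng = np.random.default_rng(14)
        x = normalize_series(rng.normal(size=40))
        y = normalize_series(rng.normal(size=40))
        cmap = fractional_cumulants(x, y)
        np.testing.assert_array_equal(cmap.cr, cmap.values.real)
        np.testing.assert_array_equal(cmap.ci, cmap.values.imag)
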