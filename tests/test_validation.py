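import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprintfusion.io_formats import GnssSeries
from sprintfusion.validation import (
    bland_altman,
    duration_error,
    fit_error,
    lin_ccc,
    resample_for_comparison,
    summarize,
    velocity_error,
)


class TestResampling:
    def test_decimation_length(self):
        t = np.arange(11) / 200.0
        v = np.arange(11.0)
        gnss = GnssSeries(t=np.array([0.0, 0.1]), v=np.array([1.0, 2.0]),
                          fs=10.0)
        t50, v50, _ = resample_for_comparison(t, v, gnss)
        assert len(t50) == 3          # indices 0, 4, 8
        assert np.array_equal(v50, v[[0, 4, 8]])

    def test_constant_series_unchanged(self):
        t = np.arange(201) / 200.0
        v = np.full(201, 4.2)
        gnss = GnssSeries(t=np.arange(11) / 10.0, v=np.full(11, 4.2), fs=10.0)
        _, v50, vg50 = resample_for_comparison(t, v, gnss)
        assert np.all(v50 == 4.2) and np.allclose(vg50, 4.2)

    def test_linear_gnss_interpolates_exactly(self):
        t = np.arange(201) / 200.0
        gnss = GnssSeries(t=np.arange(11) / 10.0,
                          v=3.0 * np.arange(11) / 10.0, fs=10.0)
        t50, _, vg50 = resample_for_comparison(t, np.zeros_like(t), gnss)
        assert np.allclose(vg50, 3.0 * t50, atol=1e-12)

    def test_no_extrapolation_beyond_gnss(self):
        t = np.arange(401) / 200.0  # 2 s of estimate
        gnss = GnssSeries(t=np.arange(11) / 10.0, v=np.ones(11), fs=10.0)
        t50, *_ = resample_for_comparison(t, np.zeros_like(t), gnss)
        assert t50[-1] <= 1.0 + 1e-12


class TestErrorVectors:
    def test_normalised_rms_hand_example(self):
        # errors (2-1)/4, (4-3)/4 -> 25% each
        assert velocity_error([2.0, 4.0], [1.0, 3.0]) == pytest.approx(25.0)

    def test_identical_series_zero_error(self):
        assert velocity_error([1, 5, 9], [1, 5, 9]) == 0.0

    def test_constant_offset_closed_form(self):
        v_ref = np.array([2.0, 5.0, 10.0])
        v_test = v_ref + 0.1 * v_ref.max()
        assert velocity_error(v_ref, v_test) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(50) * 9 + 1, rng.random(50) * 9 + 1
        assert velocity_error(3 * a, 3 * b) == pytest.approx(
            velocity_error(a, b))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            velocity_error([0.0, 0.0], [1.0, 1.0])

    def test_fit_error_constant_offset(self):
        assert fit_error([1, 2, 3], [1.5, 2.5, 3.5]) == pytest.approx(0.5)
        assert fit_error([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fit_error_consistent_with_velocity_error(self):
        rng = np.random.default_rng(1)
        ref, fitted = rng.random(40) * 8 + 1, rng.random(40) * 8 + 1
        pct = velocity_error(ref, fitted)
        assert fit_error(ref, fitted) == pytest.approx(
            pct * np.max(ref) / 100.0)

    def test_duration_error_examples(self):
        assert duration_error(8.0, 8.4) == pytest.approx(-5.0)
        assert duration_error(7.0, 7.0) == 0.0
        assert duration_error(7.0, 0.0) == 100.0
        with pytest.raises(ValueError):
            duration_error(0.0, 1.0)


class TestSummaries:
    def test_median_of_three(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.median == 2.0

    def test_linear_interpolation_percentiles(self):
        s = summarize([1.0, 2.0, 3.0, 4.0])
        assert s.median == 2.5
        assert s.iqr == (1.75, 3.25)

    def test_single_value(self):
        s = summarize([4.2])
        assert s.median == 4.2 and s.iqr == (4.2, 4.2)

    def test_quartiles_bracket_median(self, rng):
        s = summarize(rng.normal(size=101))
        assert s.iqr[0] <= s.median <= s.iqr[1]


class TestBlandAltman:
    def test_identical_series(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.bias == 0.0 and s.loa == (0.0, 0.0)

    def test_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        s = bland_altman(x, x - 0.5)
        assert s.bias == pytest.approx(0.5)
        assert s.loa[0] == pytest.approx(0.5) and s.loa[1] == pytest.approx(0.5)

    def test_symmetric_differences_hand_computation(self):
        # d = [-1, 1]: bias 0, sd = sqrt(2), loa = ±1.96·sqrt(2)
        s = bland_altman([0.0, 1.0], [1.0, 0.0])
        assert s.bias == 0.0
        assert s.loa[1] == pytest.approx(1.96 * math.sqrt(2), abs=1e-12)
        assert s.loa[0] == pytest.approx(-1.96 * math.sqrt(2), abs=1e-12)

    def test_shift_invariance(self, rng):
        x, y = rng.random(30), rng.random(30)
        a, b = bland_altman(x, y), bland_altman(x + 7.0, y + 7.0)
        assert a.bias == pytest.approx(b.bias)
        assert a.loa == pytest.approx(b.loa)

    def test_loa_bracket_bias(self, rng):
        s = bland_altman(rng.random(20), rng.random(20))
        assert s.loa[0] <= s.bias <= s.loa[1]


class TestLinCcc:
    def test_hand_computed_value(self):
        ccc, _ = lin_ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert ccc == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_perfect_agreement(self):
        ccc, _ = lin_ccc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ccc == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.array([-1.0, 0.0, 1.0])  # zero mean
        ccc, _ = lin_ccc(x, -x)
        assert ccc == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        x, y = rng.random(25), rng.random(25)
        assert lin_ccc(x, y)[0] == pytest.approx(lin_ccc(y, x)[0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30),
           st.lists(st.floats(-100, 100), min_size=4, max_size=30))
    def test_bounded_and_below_pearson(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.asarray(xs[:n])
        y = np.asarray(ys[:n])
        if x.var() == 0 or y.var() == 0:
            return
        ccc, (lo, hi) = lin_ccc(x, y)
        assert -1.0 <= ccc <= 1.0
        assert lo <= ccc <= hi
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12  # bias correction factor <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
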