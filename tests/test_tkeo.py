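"""Unit and property tests of the Teager-Kaiser energy core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mmode_tkeo import (
    MModeScan,
    ScanCalibration,
    column_stats,
    moving_average,
    rowwise_tkeo,
    span_from_seconds,
    tkeo,
    trace_from_scan,
)


class TestTkeo:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([5, 5, 5, 5], [0, 0]),  # constant -> zero energy
            ([2, 3, 5], [-1.0]),  # 3^2 - 2*5
            ([0, 2, 4, 6], [4.0, 4.0]),  # ramp slope a -> a^2
        ],
    )
    def test_hand_examples(self, x, expected):
        np.testing.assert_allclose(tkeo(x), expected)

    def test_sinusoid_closed_form(self):
        # A*cos(Omega*n) has constant energy A^2 * sin(Omega)^2
        A, omega = 2.0, np.pi / 2
        x = A * np.cos(omega * np.arange(5))
        np.testing.assert_allclose(tkeo(x), A**2 * np.sin(omega) ** 2, atol=1e-12)
        for A, omega in [(0.7, 0.3), (3.0, 1.1), (1.0, 2.5)]:
            x = A * np.cos(omega * np.arange(40) + 0.4)
            np.testing.assert_allclose(
                tkeo(x), A**2 * np.sin(omega) ** 2, atol=1e-10
            )

    def test_matches_three_term_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 50))
            x = rng.normal(size=n)
            expected = [x[k + 1] ** 2 - x[k] * x[k + 2] for k in range(n - 2)]
            np.testing.assert_allclose(tkeo(x), expected, rtol=1e-12, atol=1e-15)

    def test_scale_covariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        for c in (0.1, 2.0, -3.0):
            np.testing.assert_allclose(tkeo(c * x), c**2 * tkeo(x), rtol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tkeo([1.0, 2.0])


class TestRowwise:
    def test_delegates_to_tkeo(self):
        out = rowwise_tkeo(np.array([[2.0, 3.0, 5.0]]))
        np.testing.assert_array_equal(out, [[-1.0]])

    def test_constant_rows_zero(self):
        out = rowwise_tkeo(np.full((4, 10), 0.3))
        np.testing.assert_array_equal(out, np.zeros((4, 8)))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        img = rng.random((6, 20))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(rowwise_tkeo(img[perm]), rowwise_tkeo(img)[perm])


class TestColumnStats:
    def test_hand_example(self):
        mean, sd = column_stats(np.array([[0.0], [2.0]]))
        assert mean[0] == 1.0
        assert sd[0] == pytest.approx(np.sqrt(2.0))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        tke = rng.normal(size=(50, 200))
        mean, sd = column_stats(tke)
        for j in range(0, 200, 17):
            col = tke[:, j]
            m = sum(col) / len(col)
            s = np.sqrt(sum((v - m) ** 2 for v in col) / (len(col) - 1))
            assert mean[j] == pytest.approx(m, rel=1e-12)
            assert sd[j] == pytest.approx(s, rel=1e-12)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            column_stats(np.ones((1, 5)))


class TestSpan:
    @pytest.mark.parametrize(
        "window_s, rate, expected",
        [(0.3, 100, 31), (0.05, 100, 5), (0.1, 100, 11), (0.001, 100, 1)],
    )
    def test_examples(self, window_s, rate, expected):
        assert span_from_seconds(window_s, rate) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            span_from_seconds(0, 100)
        with pytest.raises(ValueError):
            span_from_seconds(0.3, 0)


class TestMovingAverage:
    def test_shrinking_edges_hand_example(self):
        np.testing.assert_allclose(
            moving_average(np.array([0.0, 0, 3, 0, 0]), 3), [0, 1, 1, 1, 0]
        )

    def test_linear_preserved(self):
        np.testing.assert_allclose(
            moving_average(np.arange(1.0, 6.0), 3), [1, 2, 3, 4, 5]
        )

    @given(
        x=arrays(np.float64, st.integers(1, 60),
                 elements=st.floats(-1e6, 1e6)),
        span=st.integers(0, 15).map(lambda k: 2 * k + 1),
    )
    @settings(deadline=None, max_examples=50)
    def test_constant_fixed_point_and_bounds(self, x, span):
        out = moving_average(x, span)
        assert len(out) == len(x)
        # every output is a mean of inputs, hence within their range
        assert out.min() >= x.min() - 1e-9 * max(1, abs(x.min()))
        assert out.max() <= x.max() + 1e-9 * max(1, abs(x.max()))
        const = moving_average(np.full(len(x), 3.5), span)
        np.testing.assert_allclose(const, 3.5)

    def test_periodic_interior_mean_preserved(self):
        # over whole periods inside the full-window interior, the smoothed
        # mean equals the signal mean exactly
        rng = np.random.default_rng(4)
        period, span, reps = 10, 7, 8
        x = np.tile(rng.normal(size=period), reps)
        out = moving_average(x, span)
        h = span // 2
        m = (len(x) - 2 * h) // period
        interior = out[h : h + m * period]
        assert interior.mean() == pytest.approx(x[:period].mean(), rel=1e-12)

    def test_even_span_raises(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(5), 4)


class TestTraceFromScan:
    def test_constant_scan_zero_trace(self):
        scan = MModeScan(np.full((5, 50), 0.4), ScanCalibration())
        trace = trace_from_scan(scan)
        assert len(trace) == 48
        np.testing.assert_array_equal(trace.mean_tke, 0)
        np.testing.assert_array_equal(trace.sd_tke, 0)
        np.testing.assert_array_equal(trace.sd_tke_smoothed, 0)

    def test_length_and_span(self, supra_scan, supra_trace):
        assert len(supra_trace) == supra_scan.n_columns - 2
        assert supra_trace.span == 31  # 0.3 s at 100 columns/s

    def test_stimulation_raises_sd_statistic(self, supra_trace, protocol):
        t = supra_trace.times
        plateau = (t >= 8.5) & (t <= 19.5)
        pre = t <= 5.5
        assert (
            supra_trace.sd_tke_smoothed[plateau].mean()
            > supra_trace.sd_tke_smoothed[pre].mean()
        )

    def test_trace_scale_covariance(self, null_scan):
        # halving image intensities scales energy statistics by 1/4
        half = MModeScan(null_scan.pixels / 2, null_scan.calibration)
        t1 = trace_from_scan(null_scan)
        t2 = trace_from_scan(half)
        np.testing.assert_allclose(t2.mean_tke, t1.mean_tke / 4, atol=1e-12)
        np.testing.assert_allclose(t2.sd_tke, t1.sd_tke / 4, atol=1e-12)

    def test_csv_round_trip(self, null_trace, tmp_path):
        import pandas as pd

        path = tmp_path / "trace.csv"
        null_trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "time_s", "mean_tke", "sd_tke", "mean_tke_smoothed", "sd_tke_smoothed",
        ]
        np.testing.assert_allclose(df["sd_tke"], null_trace.sd_tke)
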