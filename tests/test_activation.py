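"""Statistical machinery and the activation decision."""

import numpy as np
import pytest
from scipy import stats as sps

from mmode_tkeo import (
    MModeScan,
    ScanCalibration,
    StimProtocol,
    detect_activation,
    detect_transient_peaks,
    is_active,
    jarque_bera,
    kurtosis,
    segment_windows,
    skewness,
    trace_from_scan,
    two_sample_t,
)
from mmode_tkeo.activation import _jb_statistic, in_windows

PROT = StimProtocol(amplitude_mA=24.0)


class TestSegmentWindows:
    def test_default_guard(self):
        spec = segment_windows(PROT, 0.5)
        assert spec.baseline_windows == ((0.0, 5.5), (22.5, 28.0))
        assert spec.stim_windows == ((8.5, 19.5),)

    def test_zero_guard(self):
        spec = segment_windows(PROT, 0.0)
        assert spec.baseline_windows == ((0.0, 6.0), (22.0, 28.0))
        assert spec.stim_windows == ((8.0, 20.0),)

    def test_guard_exceeding_pause(self):
        with pytest.raises(ValueError, match="not smaller"):
            segment_windows(PROT, 7.0)

    def test_in_windows_mask(self):
        t = np.array([0.0, 5.4, 5.6, 23.0, 27.9])
        mask = in_windows(t, ((0.0, 5.5), (22.5, 28.0)))
        np.testing.assert_array_equal(mask, [True, True, False, True, True])


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_moments(self):
        # x = [0,0,0,4]: m2=3, m3=6, m4=21
        x = [0.0, 0.0, 0.0, 4.0]
        assert skewness(x) == pytest.approx(6 / 3**1.5, rel=1e-12)
        assert kurtosis(x) == pytest.approx(21 / 9, rel=1e-12)

    def test_large_normal_sample_kurtosis_three(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.02)
        assert skewness(x) == pytest.approx(0.0, abs=0.01)

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            skewness([2.0, 2.0, 2.0])


class TestJarqueBera:
    def test_statistic_from_printed_moments(self):
        # S=0.52, K=3.52, n=35 (a cohort-scale worked example)
        assert _jb_statistic(0.52, 3.52, 35) == pytest.approx(1.972, abs=5e-3)

    def test_asymptotic_p_is_chi2_tail(self):
        x = np.random.default_rng(1).standard_normal(200)
        rep = jarque_bera(x)
        assert rep.p_value == pytest.approx(np.exp(-rep.jb_statistic / 2), rel=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.gamma(2.0, size=int(rng.integers(20, 200)))
            rep = jarque_bera(x)
            ref = sps.jarque_bera(x)
            assert rep.jb_statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert rep.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monte_carlo_converges_to_asymptotic(self):
        x = np.random.default_rng(3).standard_normal(2000)
        asym = jarque_bera(x, method="asymptotic")
        mc = jarque_bera(x, method="mc", mc_reps=2000, seed=0)
        assert mc.method == "mc"
        assert abs(mc.p_value - asym.p_value) < 0.06

    def test_mc_deterministic_under_seed(self):
        x = np.random.default_rng(4).standard_normal(35)
        a = jarque_bera(x, method="mc", mc_reps=500, seed=7)
        b = jarque_bera(x, method="mc", mc_reps=500, seed=7)
        assert a.p_value == b.p_value

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            jarque_bera(np.arange(5.0))


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.ci95[0] == pytest.approx(-res.ci95[1])

    def test_hand_example(self):
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0213, abs=2e-4)
        assert res.difference == pytest.approx(3.0)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 30)))
            res = two_sample_t(a, b)
            ref = sps.ttest_ind(b, a, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-12)

    def test_ci_brackets_difference(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(1.0, size=25)
        res = two_sample_t(a, b)
        assert res.ci95[0] <= res.difference <= res.ci95[1]

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestDetectActivation:
    def test_constant_trace_inactive(self):
        scan = MModeScan(np.full((4, 2800), 0.5), ScanCalibration())
        trace = trace_from_scan(scan)
        res = detect_activation(trace, segment_windows(PROT))
        assert not res["sd_tke"].active
        assert res["sd_tke"].difference == 0.0
        assert res["sd_tke"].p_value == 1.0

    def test_supra_threshold_detected(self, supra_trace):
        res = detect_activation(supra_trace, segment_windows(PROT))
        assert res["sd_tke"].active and res["mean_tke"].active
        assert res["sd_tke"].difference > 0
        assert is_active(res) and is_active(res, "both")

    def test_result_invariants(self, supra_trace, null_trace):
        for trace in (supra_trace, null_trace):
            for res in detect_activation(trace, segment_windows(PROT)).values():
                assert res.ci95[0] <= res.difference <= res.ci95[1]
                if res.active:
                    assert res.p_value <= res.alpha and res.difference > 0

    def test_relative_increase(self, supra_trace):
        res = detect_activation(supra_trace, segment_windows(PROT))["sd_tke"]
        assert res.relative_increase_pct == pytest.approx(
            100 * (res.mean_stim - res.mean_baseline) / res.mean_baseline
        )

    def test_empty_segments_rejected(self, supra_trace):
        from mmode_tkeo import SegmentSpec

        bad = SegmentSpec(((100.0, 101.0),), ((8.5, 19.5),), 0.5)
        with pytest.raises(ValueError, match="too few"):
            detect_activation(supra_trace, bad)


class TestTransientPeaks:
    def test_onset_and_cessation_peaks(self, supra_trace):
        peaks = detect_transient_peaks(supra_trace, PROT)
        onset = peaks[(peaks >= 5.5) & (peaks <= 6.5)]
        cessation = peaks[(peaks >= 21.5) & (peaks <= 22.5)]
        assert len(onset) == 1 and len(cessation) == 1

    def test_null_scan_has_no_switching_peaks(self, null_trace):
        peaks = detect_transient_peaks(null_trace, PROT)
        assert not np.any((peaks >= 5.5) & (peaks <= 6.5))
        assert not np.any((peaks >= 21.5) & (peaks <= 22.5))

    def test_constant_trace_empty(self):
        scan = MModeScan(np.full((4, 2800), 0.5), ScanCalibration())
        peaks = detect_transient_peaks(trace_from_scan(scan), PROT)
        assert len(peaks) == 0
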