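"""Calibration and validation experiments for the detection pipeline.

Each experiment runs the full pipeline (render -> energy trace -> decision)
on simulated scans under controlled conditions and reports an operating
characteristic: the false-positive rate on unstimulated scans, detection
power as a function of contraction strength, threshold agreement across
stimulation frequencies, and confidence-interval coverage on simulated
cohorts.  All experiments are deterministic under their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .activation import detect_activation, segment_windows
from .synthetic import (
    CohortParams,
    StimProtocol,
    VirtualPatient,
    render_scan,
    sample_patient,
    simulate_cohort,
)
from .threshold import find_mt, make_simulated_stimulator
from .tkeo import trace_from_scan

__all__ = [
    "type_one_error_rate",
    "detection_rate_by_gain",
    "frequency_agreement",
    "mean_ci_coverage",
]


def _default_patient(noise_sigma: float, gain: float = 1.2) -> VirtualPatient:
    return VirtualPatient(
        mt_true_mA=23.5,
        st_true_mA=9.0,
        displacement_gain_mm=gain,
        noise_sigma=noise_sigma,
    )


def type_one_error_rate(
    n_scans: int = 200,
    seed: int = 0,
    noise_sigma: float = 0.03,
    alpha: float = 0.05,
    guard_s: float = 0.5,
) -> float:
    """False-positive rate of the activation decision on unstimulated scans.

    Renders ``n_scans`` scans with the stimulation amplitude at zero (no
    displacement, speckle noise only) and reports the fraction flagged active
    by the primary SD-of-energy criterion.  A calibrated test gives a rate
    close to ``alpha``.
    """
    protocol = StimProtocol(amplitude_mA=0.0)
    segments = segment_windows(protocol, guard_s)
    patient = _default_patient(noise_sigma)
    seeder = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_scans):
        scan = render_scan(patient, protocol, seed=int(seeder.integers(2**31)))
        trace = trace_from_scan(scan)
        results = detect_activation(trace, segments, alpha=alpha)
        hits += results["sd_tke"].active
    return hits / n_scans


def detection_rate_by_gain(
    gains_mm: tuple[float, ...] = (0.2, 0.6, 1.2),
    n_seeds: int = 100,
    seed: int = 0,
    noise_sigma: float = 0.03,
    alpha: float = 0.05,
    guard_s: float = 0.5,
) -> dict[float, float]:
    """Detection rate of supra-threshold scans at several contraction gains.

    For each displacement gain, renders ``n_seeds`` scans at the motor
    threshold amplitude and reports the fraction detected.  Power should be
    non-decreasing in the gain.
    """
    protocol = StimProtocol(amplitude_mA=24.0)
    segments = segment_windows(protocol, guard_s)
    rates: dict[float, float] = {}
    for gain in gains_mm:
        patient = _default_patient(noise_sigma, gain=gain)
        seeder = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_seeds):
            scan = render_scan(patient, protocol, seed=int(seeder.integers(2**31)))
            trace = trace_from_scan(scan)
            hits += detect_activation(trace, segments, alpha=alpha)["sd_tke"].active
        rates[gain] = hits / n_seeds
    return rates


def frequency_agreement(
    n_patients: int = 5,
    seed: int = 0,
    noise_sigma: float = 0.02,
    frequencies_Hz: tuple[float, float] = (60.0, 120.0),
) -> pd.DataFrame:
    """Motor thresholds of the same patients at two pulse frequencies.

    Runs the staircase search twice per patient - once per frequency, with
    identical scan seeds - and tabulates both estimates.  The contraction
    model is frequency-independent, so the pipeline must return identical
    thresholds; a disagreement would mean the frequency leaks into the
    detection path.
    """
    params = CohortParams(noise_sigma=noise_sigma)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        patient = sample_patient(rng, params)
        st = float(max(round(patient.st_true_mA), 1))
        scan_seed = int(rng.integers(2**31))
        estimates = {}
        for f in frequencies_Hz:
            stimulate = make_simulated_stimulator(
                patient, StimProtocol(frequency_Hz=f), seed=scan_seed
            )
            estimates[f] = find_mt(stimulate, st_mA=st).mt_mA
        rows.append(
            {
                "patient": i,
                "mt_true": patient.mt_true_mA,
                **{f"mt_at_{int(f)}Hz": estimates[f] for f in frequencies_Hz},
                "agree": len(set(estimates.values())) == 1,
            }
        )
    return pd.DataFrame(rows)


def mean_ci_coverage(
    n_cohorts: int = 200,
    n: int = 35,
    seed: int = 0,
    params: CohortParams | None = None,
) -> float:
    """Coverage of the nominal-95% CI for the mean motor threshold.

    Simulates ``n_cohorts`` cohorts of ``n`` patients, forms the Student
    interval ``sample mean +/- t(0.975, n-1) * SE`` for each, and reports the
    percentage covering the true population mean (the analytic mean of the
    truncated sampling distribution).  The t quantile, not 1.96, is the
    correct nominal-95% multiplier at cohort sizes of a few dozen.
    """
    params = params if params is not None else CohortParams()
    true_mean = params.mt.truncated_mean
    tcrit = float(stats.t.ppf(0.975, n - 1))
    seeder = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_cohorts):
        table = simulate_cohort(n, int(seeder.integers(2**31)), params)
        mt = table["mt_mA"].to_numpy()
        se = mt.std(ddof=1) / np.sqrt(n)
        covered += abs(mt.mean() - true_mean) <= tcrit * se
    return 100.0 * covered / n_cohorts
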