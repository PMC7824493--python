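"""Motor-threshold search over a stimulate-and-scan callback.

The motor threshold (MT) is the smallest stimulation amplitude that elicits
a contraction detectable on the M-mode scan.  The search mirrors the
clinical protocol: start at twice the sensory threshold (ST); if no response,
ascend in fixed steps until a level is confirmed active; if there is a
response at the start, descend until a level is inactive and report the
smallest active level visited.  A level is confirmed only when all
``replicates`` independent scans at that amplitude test active (a majority
rule is available), so a single noisy scan cannot fix the threshold.

The callback abstraction means the same algorithm drives either the
simulator (below) or, in principle, a live acquisition loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .activation import ActivationResult, detect_activation, is_active, segment_windows
from .scan_io import ScanCalibration
from .synthetic import (
    CohortParams,
    MotionArtifactSpec,
    StimProtocol,
    TissueProfile,
    VirtualPatient,
    render_scan,
    sample_patient,
)
from .tkeo import trace_from_scan

__all__ = [
    "ThresholdResult",
    "find_mt",
    "make_simulated_stimulator",
    "threshold_recovery_experiment",
]

Stimulator = Callable[[float], ActivationResult]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of one motor-threshold search.

    ``found`` is False when no level up to ``max_mA`` was confirmed active;
    ``mt_mA`` and ``ratio`` are then ``None`` ("no motor response"), never a
    fabricated number.  ``trajectory`` records every tested level in order as
    ``(amplitude_mA, level_active)`` pairs.
    """

    st_mA: float
    mt_mA: float | None
    ratio: float | None
    trajectory: tuple[tuple[float, bool], ...]
    replicates_per_level: int
    found: bool

    def to_dict(self) -> dict:
        return {
            "st_mA": self.st_mA,
            "mt_mA": self.mt_mA,
            "ratio": self.ratio,
            "found": self.found,
            "replicates_per_level": self.replicates_per_level,
            "trajectory": [
                {"amplitude_mA": a, "active": act} for a, act in self.trajectory
            ],
        }


def _test_level(
    stimulate: Stimulator, amplitude: float, replicates: int, rule: str
) -> bool:
    """Confirm one amplitude level, short-circuiting once decided."""
    needed = replicates if rule == "all" else replicates // 2 + 1
    active = 0
    for i in range(replicates):
        if stimulate(amplitude).active:
            active += 1
        if active >= needed:
            return True
        if active + (replicates - 1 - i) < needed:
            return False
    return active >= needed


def find_mt(
    stimulate: Stimulator,
    st_mA: float,
    step_mA: float = 1.0,
    max_mA: float = 100.0,
    replicates: int = 3,
    rule: str = "all",
) -> ThresholdResult:
    """Locate the motor threshold by the twice-ST staircase protocol.

    Starting at ``2 * st_mA``: if that level is inactive, ascend by
    ``step_mA`` until the first confirmed-active level (the MT); if it is
    active, descend until the first inactive level and report the smallest
    active level visited.  At most ``max_mA / step_mA`` levels are ever
    stimulated.
    """
    if st_mA <= 0:
        raise ValueError(f"st_mA must be > 0, got {st_mA}")
    if step_mA <= 0:
        raise ValueError(f"step_mA must be > 0, got {step_mA}")
    if max_mA <= 2 * st_mA:
        raise ValueError(f"max_mA={max_mA} must exceed twice st_mA={st_mA}")
    if rule not in ("all", "majority"):
        raise ValueError(f"rule must be 'all' or 'majority', got {rule!r}")
    trajectory: list[tuple[float, bool]] = []
    amplitude = 2.0 * st_mA
    start_active = _test_level(stimulate, amplitude, replicates, rule)
    trajectory.append((amplitude, start_active))
    if not start_active:
        # ascending branch: MT = first confirmed-active level
        while amplitude + step_mA <= max_mA + 1e-9:
            amplitude += step_mA
            active = _test_level(stimulate, amplitude, replicates, rule)
            trajectory.append((amplitude, active))
            if active:
                return ThresholdResult(
                    st_mA, amplitude, amplitude / st_mA, tuple(trajectory),
                    replicates, True,
                )
        return ThresholdResult(st_mA, None, None, tuple(trajectory), replicates, False)
    # descending branch: MT = smallest active level visited
    last_active = amplitude
    while amplitude - step_mA > 1e-9:
        amplitude -= step_mA
        active = _test_level(stimulate, amplitude, replicates, rule)
        trajectory.append((amplitude, active))
        if not active:
            break
        last_active = amplitude
    return ThresholdResult(
        st_mA, last_active, last_active / st_mA, tuple(trajectory), replicates, True
    )


def make_simulated_stimulator(
    patient: VirtualPatient,
    protocol: StimProtocol | None = None,
    *,
    profile: TissueProfile | None = None,
    calib: ScanCalibration | None = None,
    artifacts: MotionArtifactSpec | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    guard_s: float = 0.5,
    window_s: float = 0.3,
    depth_extent_mm: float = 20.0,
    criterion: str = "sd_tke",
) -> Stimulator:
    """Build a stimulate-and-scan callback backed by the scan simulator.

    Each call renders one scan of ``patient`` at the requested amplitude with
    a fresh sub-seed (so replicates see independent speckle noise), runs the
    energy-trace pipeline and returns the activation result for the primary
    statistic.  The whole sequence of calls is deterministic under ``seed``.
    """
    protocol = protocol if protocol is not None else StimProtocol()
    seeder = np.random.default_rng(seed)
    segments = segment_windows(protocol, guard_s)

    def stimulate(amplitude_mA: float) -> ActivationResult:
        scan = render_scan(
            patient,
            protocol.with_amplitude(amplitude_mA),
            profile=profile,
            calib=calib,
            artifacts=artifacts,
            seed=int(seeder.integers(2**31)),
            depth_extent_mm=depth_extent_mm,
        )
        trace = trace_from_scan(scan, window_s)
        results = detect_activation(trace, segments, alpha=alpha)
        if criterion not in results:
            raise ValueError(f"unknown criterion {criterion!r}")
        return results[criterion]

    return stimulate


def threshold_recovery_experiment(
    n_patients: int,
    seed: int,
    noise_sigma: float = 0.02,
    *,
    params: CohortParams | None = None,
    step_mA: float = 1.0,
    max_mA: float = 100.0,
    replicates: int = 3,
    frequency_Hz: float = 60.0,
) -> pd.DataFrame:
    """Sample patients, run the MT search on rendered scans, report errors.

    The sensory threshold fed to the search is the latent ST rounded to the
    nearest milliamp (it is a patient report, not an imaging quantity).
    Returns one row per patient with ``mt_true``, ``mt_estimated``, the
    estimation error, the estimated MT/ST ratio and the number of levels
    stimulated; fully reproducible under ``seed``.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    base = params if params is not None else CohortParams()
    params = replace(base, noise_sigma=noise_sigma)
    rng = np.random.default_rng(seed)
    protocol = StimProtocol(frequency_Hz=frequency_Hz)
    rows = []
    for i in range(n_patients):
        patient = sample_patient(rng, params)
        st_reported = max(round(patient.st_true_mA), 1)
        stimulate = make_simulated_stimulator(
            patient, protocol, seed=int(rng.integers(2**31))
        )
        res = find_mt(
            stimulate,
            st_mA=float(st_reported),
            step_mA=step_mA,
            max_mA=max_mA,
            replicates=replicates,
        )
        rows.append(
            {
                "patient": i,
                "mt_true": patient.mt_true_mA,
                "st_reported": float(st_reported),
                "mt_estimated": res.mt_mA,
                "error_mA": None if res.mt_mA is None else res.mt_mA - patient.mt_true_mA,
                "ratio_estimated": res.ratio,
                "n_levels": len(res.trajectory),
                "found": res.found,
            }
        )
    return pd.DataFrame(rows)
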