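"""Synthetic M-mode scans of virtual patients undergoing electrical stimulation.

The generator emulates what a portable scanner shows while a muscle is driven
by neuromuscular electrical stimulation (NMES):

* a layered resting texture - bright (hyperechoic, connective-tissue) bands
  over a darker background, modelled as Gaussian bumps in depth;
* an all-or-none contraction: when the pulse amplitude reaches the patient's
  latent motor threshold, tissue layers are displaced in depth in proportion
  to the stimulation envelope (ramp up during the surge, sustained during the
  plateau, ramp down during the shrink), with optional within-plateau jitter
  and brief onset/cessation twitches that reproduce the narrow energy peaks
  seen when stimulation switches on and off;
* additive zero-mean Gaussian speckle noise, clipped to the dynamic range;
* optional transducer-motion artifacts: smooth global depth drifts occurring
  at random times, uncorrelated with the stimulation envelope.

Everything is deterministic under a seed, so the downstream detection,
threshold-search and cohort statistics can be exercised end-to-end without
clinical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan_io import MModeScan, ScanCalibration

__all__ = [
    "StimProtocol",
    "VirtualPatient",
    "TissueProfile",
    "MotionArtifactSpec",
    "TruncatedNormal",
    "CohortParams",
    "envelope",
    "contraction_displacement",
    "render_scan",
    "sample_patient",
    "simulate_cohort",
]


@dataclass(frozen=True)
class StimProtocol:
    """Timing envelope and pulse parameters of one NMES sequence.

    The default sequence is a 6 s pause, a 2 s surge during which the pulse
    amplitude ramps linearly from 0 to its set value, a 12 s full-amplitude
    plateau, a 2 s shrink back to 0, and a final 6 s pause - 28 s in total.
    Pulses are 350 us wide at 60 or 120 Hz; pulse width and frequency do not
    enter the displacement model (thresholds are frequency-independent here).
    """

    pause_pre_s: float = 6.0
    surge_s: float = 2.0
    plateau_s: float = 12.0
    shrink_s: float = 2.0
    pause_post_s: float = 6.0
    amplitude_mA: float = 0.0
    frequency_Hz: float = 60.0
    pulse_width_us: float = 350.0

    def __post_init__(self) -> None:
        for name in ("pause_pre_s", "surge_s", "plateau_s", "shrink_s", "pause_post_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.amplitude_mA < 0:
            raise ValueError(f"amplitude_mA must be >= 0, got {self.amplitude_mA}")

    @property
    def total_duration_s(self) -> float:
        return (
            self.pause_pre_s
            + self.surge_s
            + self.plateau_s
            + self.shrink_s
            + self.pause_post_s
        )

    @property
    def surge_start_s(self) -> float:
        return self.pause_pre_s

    @property
    def plateau_start_s(self) -> float:
        return self.pause_pre_s + self.surge_s

    @property
    def shrink_start_s(self) -> float:
        return self.plateau_start_s + self.plateau_s

    @property
    def shrink_end_s(self) -> float:
        return self.shrink_start_s + self.shrink_s

    def with_amplitude(self, amplitude_mA: float) -> "StimProtocol":
        return replace(self, amplitude_mA=amplitude_mA)


@dataclass(frozen=True)
class VirtualPatient:
    """Latent physiology and anthropometrics of one simulated subject.

    ``st_true_mA`` and ``mt_true_mA`` are the latent sensory and motor
    thresholds; contraction is all-or-none at ``mt_true_mA``.
    ``displacement_gain_mm`` is the peak depth displacement of tissue layers
    at full stimulation, ``noise_sigma`` the speckle-noise scale on the
    [0, 1] intensity range.
    """

    mt_true_mA: float
    st_true_mA: float
    displacement_gain_mm: float = 1.2
    noise_sigma: float = 0.03
    bmi: float = 30.2
    sat_mm: float = 12.0
    age_y: float = 64.0

    def __post_init__(self) -> None:
        if not (self.mt_true_mA > self.st_true_mA > 0):
            raise ValueError(
                "need mt_true_mA > st_true_mA > 0, got "
                f"mt={self.mt_true_mA}, st={self.st_true_mA}"
            )
        if self.displacement_gain_mm < 0 or self.noise_sigma < 0:
            raise ValueError("displacement_gain_mm and noise_sigma must be >= 0")

    @property
    def ratio(self) -> float:
        return self.mt_true_mA / self.st_true_mA


@dataclass(frozen=True)
class TissueProfile:
    """Depth profile of the resting echo texture.

    Bright connective-tissue interfaces are Gaussian bumps of peak brightness
    ``band_intensities`` centred at ``band_centers_mm`` with standard
    deviation ``band_widths_mm``, on top of a uniform ``background``.
    """

    band_centers_mm: tuple[float, ...]
    band_widths_mm: tuple[float, ...]
    band_intensities: tuple[float, ...]
    background: float = 0.12

    def __post_init__(self) -> None:
        n = len(self.band_centers_mm)
        if len(self.band_widths_mm) != n or len(self.band_intensities) != n:
            raise ValueError("band parameter lists must have equal length")
        if list(self.band_centers_mm) != sorted(self.band_centers_mm):
            raise ValueError("bands must be sorted by depth")
        if any(w <= 0 for w in self.band_widths_mm):
            raise ValueError("band widths must be > 0")
        if self.background < 0 or any(
            a < 0 or a + self.background > 1 for a in self.band_intensities
        ):
            raise ValueError("intensities must keep the image within [0, 1]")

    @classmethod
    def default(cls) -> "TissueProfile":
        """Five echogenic bands spread over the 20-40 mm analysis window."""
        return cls(
            band_centers_mm=(22.5, 26.0, 30.0, 34.0, 38.0),
            band_widths_mm=(0.4, 0.5, 0.45, 0.55, 0.4),
            band_intensities=(0.55, 0.70, 0.60, 0.65, 0.50),
            background=0.12,
        )

    def evaluate(self, z_mm: np.ndarray) -> np.ndarray:
        """Resting intensity at depths ``z_mm`` (any array shape)."""
        out = np.full_like(np.asarray(z_mm, dtype=float), self.background)
        for c, w, a in zip(
            self.band_centers_mm, self.band_widths_mm, self.band_intensities
        ):
            out += a * np.exp(-0.5 * ((z_mm - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class MotionArtifactSpec:
    """Transducer-motion episodes: smooth global depth drifts.

    Episode count per scan is Poisson with mean ``rate_per_scan``; each
    episode is a half-cosine drift of magnitude ``drift_amplitude_mm``
    lasting ``episode_duration_s``, starting at a uniformly random time,
    deliberately uncorrelated with the stimulation envelope.
    """

    rate_per_scan: float = 1.0
    episode_duration_s: float = 1.5
    drift_amplitude_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rate_per_scan, self.episode_duration_s, self.drift_amplitude_mm) < 0:
            raise ValueError("all artifact parameters must be >= 0")


def envelope(protocol: StimProtocol, t: float | np.ndarray) -> float | np.ndarray:
    """Normalised stimulation envelope in [0, 1] at time(s) ``t`` seconds.

    Zero during the pauses, a linear 0-to-1 ramp across the surge, one during
    the plateau, a linear 1-to-0 ramp across the shrink; continuous
    everywhere.  Times outside ``[0, total_duration_s]`` raise ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    total = protocol.total_duration_s
    if np.any(t_arr < -1e-9) or np.any(t_arr > total + 1e-9):
        raise ValueError(f"time outside the scan window [0, {total}] s")
    env = np.zeros_like(t_arr)
    if protocol.surge_s > 0:
        in_surge = (t_arr >= protocol.surge_start_s) & (t_arr < protocol.plateau_start_s)
        env = np.where(
            in_surge, (t_arr - protocol.surge_start_s) / protocol.surge_s, env
        )
    in_plateau = (t_arr >= protocol.plateau_start_s) & (t_arr < protocol.shrink_start_s)
    env = np.where(in_plateau, 1.0, env)
    if protocol.shrink_s > 0:
        in_shrink = (t_arr >= protocol.shrink_start_s) & (t_arr < protocol.shrink_end_s)
        env = np.where(
            in_shrink, 1.0 - (t_arr - protocol.shrink_start_s) / protocol.shrink_s, env
        )
    return float(env) if np.isscalar(t) or t_arr.ndim == 0 else env


def contraction_displacement(
    patient: VirtualPatient,
    protocol: StimProtocol,
    t: float | np.ndarray,
    *,
    jitter: bool = True,
    jitter_fraction: float = 0.2,
    jitter_freq_hz: float = 12.0,
    transients: bool = True,
    transient_fraction: float = 1.0,
    transient_duration_s: float = 0.12,
) -> float | np.ndarray:
    """Depth displacement (mm) of tissue layers at time(s) ``t``.

    The contraction is all-or-none: below the latent motor threshold the
    displacement is identically zero (a 10% drop below threshold abolishes
    the response); at or above it the layers follow
    ``displacement_gain_mm * envelope(t)``.  Two optional terms emulate the
    dynamics of an electrically driven contraction:

    * ``jitter`` - a sinusoidal wobble of amplitude
      ``jitter_fraction * gain`` at ``jitter_freq_hz`` during the plateau,
      standing in for the sustained texture change of a held contraction;
    * ``transients`` - brief half-sine twitches of amplitude
      ``transient_fraction * gain`` at motion onset (surge start) and
      cessation (shrink end), reproducing the narrow on/off energy peaks of
      simultaneous motor-unit recruitment and release.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if protocol.amplitude_mA < patient.mt_true_mA:
        disp = np.zeros_like(t_arr)
    else:
        gain = patient.displacement_gain_mm
        disp = gain * np.asarray(envelope(protocol, t_arr), dtype=float)
        if jitter and protocol.plateau_s > 0:
            in_plateau = (t_arr >= protocol.plateau_start_s) & (
                t_arr < protocol.shrink_start_s
            )
            disp += np.where(
                in_plateau,
                jitter_fraction
                * gain
                * np.sin(2 * np.pi * jitter_freq_hz * (t_arr - protocol.plateau_start_s)),
                0.0,
            )
        if transients and transient_duration_s > 0:
            d = transient_duration_s
            for t0 in (protocol.surge_start_s, protocol.shrink_end_s - d):
                u = (t_arr - t0) / d
                in_burst = (u >= 0) & (u <= 1)
                disp += np.where(
                    in_burst, transient_fraction * gain * np.sin(np.pi * u), 0.0
                )
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(disp[0])
    return disp


DEFAULT_CALIBRATION = ScanCalibration(
    mm_per_row=0.042, columns_per_second=100.0, depth_offset_mm=20.0
)


def _artifact_drift(
    rng: np.random.Generator,
    artifacts: MotionArtifactSpec,
    t: np.ndarray,
    total_s: float,
) -> np.ndarray:
    """Summed drift (mm) of all artifact episodes; consumes rng draws."""
    drift = np.zeros_like(t)
    n_episodes = rng.poisson(artifacts.rate_per_scan)
    for _ in range(n_episodes):
        start = rng.uniform(0.0, max(total_s - artifacts.episode_duration_s, 0.0))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        u = (t - start) / max(artifacts.episode_duration_s, 1e-12)
        in_ep = (u >= 0) & (u <= 1)
        # half-cosine bump: drifts out and back smoothly
        drift += np.where(
            in_ep,
            sign * artifacts.drift_amplitude_mm * 0.5 * (1 - np.cos(2 * np.pi * u)),
            0.0,
        )
    return drift


def render_scan(
    patient: VirtualPatient,
    protocol: StimProtocol,
    profile: TissueProfile | None = None,
    calib: ScanCalibration | None = None,
    artifacts: MotionArtifactSpec | None = None,
    seed: int = 0,
    *,
    depth_extent_mm: float = 20.0,
    **displacement_kwargs,
) -> MModeScan:
    """Render one M-mode scan of ``patient`` under ``protocol``.

    The image has ``round(depth_extent_mm / mm_per_row)`` rows starting at
    the calibration's depth offset and ``round(total_duration * rate)``
    columns.  The column at time ``t`` is the resting depth profile evaluated
    at ``z - delta(t)`` where ``delta`` combines the contraction displacement
    and any active motion-artifact drift, plus clipped Gaussian speckle noise
    of scale ``patient.noise_sigma``.  Identical arguments and seed give
    bit-identical images.
    """
    profile = profile if profile is not None else TissueProfile.default()
    calib = calib if calib is not None else DEFAULT_CALIBRATION
    if depth_extent_mm <= 0:
        raise ValueError(f"depth_extent_mm must be > 0, got {depth_extent_mm}")
    n_rows = int(round(depth_extent_mm / calib.mm_per_row))
    n_cols = int(round(protocol.total_duration_s * calib.columns_per_second))
    if n_cols < 3:
        raise ValueError("protocol too short: scan would have fewer than 3 columns")
    rng = np.random.default_rng(seed)
    t = np.arange(n_cols) / calib.columns_per_second
    delta = np.atleast_1d(
        np.asarray(
            contraction_displacement(patient, protocol, t, **displacement_kwargs),
            dtype=float,
        )
    )
    if artifacts is not None and artifacts.rate_per_scan > 0:
        delta = delta + _artifact_drift(rng, artifacts, t, protocol.total_duration_s)
    z = calib.depth_offset_mm + np.arange(n_rows) * calib.mm_per_row
    # evaluate the depth profile through a fine lookup table (grid step of
    # mm_per_row / 8): interpolation error < 1e-4 intensity, far below the
    # speckle scale, and much faster than evaluating every band everywhere
    h = calib.mm_per_row / 8.0
    lo = z[0] - float(delta.max()) - h
    hi = z[-1] - float(delta.min()) + h
    grid = np.arange(lo, hi + h, h)
    table = profile.evaluate(grid)
    image = np.interp(z[:, None] - delta[None, :], grid, table)
    if patient.noise_sigma > 0:
        image = image + rng.normal(0.0, patient.noise_sigma, size=image.shape)
    return MModeScan(pixels=np.clip(image, 0.0, 1.0), calibration=calib)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal distribution truncated to ``[lo, hi]``."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")

    @property
    def truncated_mean(self) -> float:
        """Analytic mean of the truncated distribution."""
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def sample(self, rng: np.random.Generator) -> float:
        """One draw by rejection (deterministic for a given rng state)."""
        while True:
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return x


@dataclass(frozen=True)
class CohortParams:
    """Population parameters of the simulated cohort.

    Defaults follow the descriptive statistics of a 35-subject NMES cohort:
    motor threshold 23.4 +/- 4.94 mA on (13, 36); motor-to-sensory ratio
    2.69 +/- 0.57 on (1.5, 4.5); BMI 30.2 +/- 6.7 kg/m2 on (16.7, 47.5); age
    63.8 +/- 14.1 y on (25, 84).  Subcutaneous adipose thickness over the
    quadriceps is not tabulated in that cohort; 12 +/- 5 mm on (3, 30) is a
    realistic choice for an overweight adult population.  Thresholds are
    sampled independently of BMI and SAT by default (the observed
    correlations are near zero); BMI and SAT themselves are correlated.
    """

    mt: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(23.4, 4.94, 13.0, 36.0)
    )
    ratio: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(2.69, 0.57, 1.5, 4.5)
    )
    bmi: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(30.2, 6.7, 16.7, 47.5)
    )
    sat: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(12.0, 5.0, 3.0, 30.0)
    )
    age: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(63.8, 14.1, 25.0, 84.0)
    )
    bmi_sat_corr: float = 0.5
    displacement_gain_mm: float = 1.2
    noise_sigma: float = 0.03


def _sample_bmi_sat(
    rng: np.random.Generator, params: CohortParams
) -> tuple[float, float]:
    """Correlated BMI/SAT pair, rejected jointly until both are in range."""
    rho = params.bmi_sat_corr
    while True:
        z1 = rng.standard_normal()
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal()
        bmi = params.bmi.mean + params.bmi.sd * z1
        sat = params.sat.mean + params.sat.sd * z2
        if params.bmi.lo <= bmi <= params.bmi.hi and params.sat.lo <= sat <= params.sat.hi:
            return bmi, sat


def sample_patient(
    rng: np.random.Generator, params: CohortParams | None = None
) -> VirtualPatient:
    """Draw one virtual patient from the cohort distribution.

    The motor threshold and the motor-to-sensory ratio are truncated-normal
    draws; the sensory threshold is ``mt / ratio``, which guarantees
    ``st < mt``.  Thresholds are independent of the anthropometrics.
    """
    params = params if params is not None else CohortParams()
    mt = params.mt.sample(rng)
    ratio = params.ratio.sample(rng)
    bmi, sat = _sample_bmi_sat(rng, params)
    age = params.age.sample(rng)
    return VirtualPatient(
        mt_true_mA=mt,
        st_true_mA=mt / ratio,
        displacement_gain_mm=params.displacement_gain_mm,
        noise_sigma=params.noise_sigma,
        bmi=bmi,
        sat_mm=sat,
        age_y=age,
    )


def simulate_cohort(
    n: int, seed: int, params: CohortParams | None = None
) -> pd.DataFrame:
    """Simulate a cohort table of ``n`` patients, reproducible under ``seed``.

    Columns: ``id, mt_mA, st_mA, ratio, bmi, sat_mm, sex, age_y``.
    """
    if n < 2:
        raise ValueError(f"a cohort needs at least 2 patients, got {n}")
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        p = sample_patient(rng, params)
        rows.append(
            {
                "id": f"P{i + 1:03d}",
                "mt_mA": p.mt_true_mA,
                "st_mA": p.st_true_mA,
                "ratio": p.ratio,
                "bmi": p.bmi,
                "sat_mm": p.sat_mm,
                "sex": "F" if rng.random() < 0.5 else "M",
                "age_y": p.age_y,
            }
        )
    return pd.DataFrame(rows)
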