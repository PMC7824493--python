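"""Deciding whether a muscle contraction occurred.

The decision compares baseline segments of a Teager-Kaiser energy trace (the
pauses before and after stimulation) against the stimulation plateau, using a
pooled-variance two-sample t-test on the per-instant trace statistics.  The
across-depth SD of the energy outputs is the primary contraction indicator;
the across-depth mean is tested alongside it.

Two details matter for calibration:

* the t-test is run on the *unsmoothed* per-column statistics, decimated to
  every third column.  Adjacent energy outputs share two of their three
  pixel columns, which makes the per-column statistics serially dependent
  and the t-test anti-conservative; at stride 3 the operator windows are
  disjoint, so under speckle-only conditions the tested samples are
  independent and the test holds its nominal level.  Moving-average
  smoothing (used for display and peak finding) would induce far stronger
  serial correlation and is never fed to the test.
* the reported p-value is one-sided for an *increase* of the statistic under
  stimulation, since activation is directional; the decision is
  ``p <= alpha and difference > 0``.  The confidence interval for the
  difference stays two-sided at 95%.

Normality assessment uses the Jarque-Bera test, with either the asymptotic
chi-square(2) p-value or a seeded Monte-Carlo null calibrated at the actual
sample size (the asymptotic p is anti-conservative for a few dozen samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .synthetic import StimProtocol
from .tkeo import TKEOTrace

__all__ = [
    "SegmentSpec",
    "ActivationResult",
    "NormalityReport",
    "TTestResult",
    "segment_windows",
    "in_windows",
    "skewness",
    "kurtosis",
    "jarque_bera",
    "two_sample_t",
    "detect_activation",
    "is_active",
    "detect_transient_peaks",
]

Window = tuple[float, float]


@dataclass(frozen=True)
class SegmentSpec:
    """Baseline and stimulation time windows, with guard margins applied."""

    baseline_windows: tuple[Window, ...]
    stim_windows: tuple[Window, ...]
    guard_s: float


def segment_windows(protocol: StimProtocol, guard_s: float = 0.5) -> SegmentSpec:
    """Baseline (pauses) and stimulation (plateau) windows of a protocol.

    Both pauses form the baseline, trimmed by ``guard_s`` at the boundary
    shared with the surge/shrink ramps; the plateau forms the stimulation
    segment, trimmed by ``guard_s`` on both sides.  The ramps themselves are
    excluded entirely: the narrow on/off energy transients they host are
    activation markers, not steady-state texture change.
    """
    if guard_s < 0:
        raise ValueError(f"guard_s must be >= 0, got {guard_s}")
    phases = {
        "pause_pre_s": protocol.pause_pre_s,
        "surge_s": protocol.surge_s,
        "plateau_s": protocol.plateau_s,
        "shrink_s": protocol.shrink_s,
        "pause_post_s": protocol.pause_post_s,
    }
    for name, dur in phases.items():
        if guard_s >= dur:
            raise ValueError(f"guard_s={guard_s} is not smaller than {name}={dur}")
    if 2 * guard_s >= protocol.plateau_s:
        raise ValueError(
            f"guard_s={guard_s} leaves no plateau samples "
            f"(plateau {protocol.plateau_s} s)"
        )
    baseline = (
        (0.0, protocol.surge_start_s - guard_s),
        (protocol.shrink_end_s + guard_s, protocol.total_duration_s),
    )
    stim = ((protocol.plateau_start_s + guard_s, protocol.shrink_start_s - guard_s),)
    return SegmentSpec(baseline_windows=baseline, stim_windows=stim, guard_s=guard_s)


def in_windows(times: np.ndarray, windows: tuple[Window, ...]) -> np.ndarray:
    """Boolean mask of times falling inside any of the closed intervals."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for t0, t1 in windows:
        mask |= (times >= t0) & (times <= t1)
    return mask


def _central_moments(x: np.ndarray) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0:
        raise ValueError("sample has zero variance")
    return m2, float(np.mean(d**3)), float(np.mean(d**4))


def skewness(x: np.ndarray) -> float:
    """Moment-based skewness ``m3 / m2**1.5`` with 1/n central moments."""
    m2, m3, _ = _central_moments(x)
    return m3 / m2**1.5


def kurtosis(x: np.ndarray) -> float:
    """Raw (non-excess) kurtosis ``m4 / m2**2``; a normal sample gives ~3."""
    m2, _, m4 = _central_moments(x)
    return m4 / m2**2


@dataclass(frozen=True)
class NormalityReport:
    """Jarque-Bera normality assessment of one sample."""

    jb_statistic: float
    p_value: float
    skewness: float
    kurtosis: float  # raw; 3 for a normal distribution
    method: str  # "asymptotic" or "mc"
    n: int


def _jb_statistic(s: float, k: float, n: int) -> float:
    return n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)


def jarque_bera(
    x: np.ndarray,
    method: str = "asymptotic",
    mc_reps: int = 10_000,
    seed: int | None = None,
) -> NormalityReport:
    """Jarque-Bera test ``JB = n/6 * (S^2 + (K-3)^2 / 4)``.

    ``method='asymptotic'`` takes the p-value from the chi-square(2) tail,
    ``exp(-JB/2)``.  ``method='mc'`` calibrates it against ``mc_reps`` seeded
    standard-normal samples of the same size, which is preferable for small
    n where the asymptotic p is anti-conservative.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"Jarque-Bera needs at least 8 samples, got {x.size}")
    s, k = skewness(x), kurtosis(x)
    jb = _jb_statistic(s, k, x.size)
    if method == "asymptotic":
        p = float(stats.chi2.sf(jb, df=2))
    elif method == "mc":
        rng = np.random.default_rng(seed)
        null = rng.standard_normal((mc_reps, x.size))
        d = null - null.mean(axis=1, keepdims=True)
        m2 = np.mean(d**2, axis=1)
        s0 = np.mean(d**3, axis=1) / m2**1.5
        k0 = np.mean(d**4, axis=1) / m2**2
        jb_null = _jb_statistic(s0, k0, x.size)
        p = float((1 + np.sum(jb_null >= jb)) / (mc_reps + 1))
    else:
        raise ValueError(f"method must be 'asymptotic' or 'mc', got {method!r}")
    return NormalityReport(
        jb_statistic=jb, p_value=p, skewness=s, kurtosis=k, method=method, n=x.size
    )


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test for ``mean(b) - mean(a)``."""

    t: float
    df: int
    p_value: float  # two-sided
    difference: float  # mean(b) - mean(a)
    ci95: tuple[float, float]


def two_sample_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Student's pooled two-sample t-test with a 95% CI for the difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("pooled variance is zero; t-test undefined")
    se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    diff = float(b.mean() - a.mean())
    t = diff / se
    p = 2 * float(stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df)) * se
    return TTestResult(
        t=float(t), df=df, p_value=p, difference=diff, ci95=(diff - half, diff + half)
    )


@dataclass(frozen=True)
class ActivationResult:
    """Baseline-versus-stimulation comparison of one trace statistic.

    ``p_value`` is one-sided for an increase under stimulation; ``ci95`` is
    the two-sided 95% interval for the true difference of segment means.
    """

    statistic_name: str
    mean_baseline: float
    mean_stim: float
    difference: float
    ci95: tuple[float, float]
    p_value: float
    t: float
    df: int
    active: bool
    alpha: float
    n_baseline: int
    n_stim: int

    @property
    def relative_increase_pct(self) -> float:
        """Increase of the stimulation average relative to baseline, in %."""
        return 100.0 * self.difference / self.mean_baseline

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "mean_baseline": self.mean_baseline,
            "mean_stim": self.mean_stim,
            "difference": self.difference,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "t": self.t,
            "df": self.df,
            "active": self.active,
            "alpha": self.alpha,
            "n_baseline": self.n_baseline,
            "n_stim": self.n_stim,
        }


def detect_activation(
    trace: TKEOTrace,
    segments: SegmentSpec,
    alpha: float = 0.05,
    use_smoothed: bool = False,
    statistics: tuple[str, ...] = ("sd_tke", "mean_tke"),
    decimate: int = 3,
) -> dict[str, ActivationResult]:
    """Test each trace statistic for an increase under stimulation.

    Returns one :class:`ActivationResult` per tested statistic.  Each result
    is flagged ``active`` when its one-sided p-value is at most ``alpha`` and
    the difference is positive; combine them with :func:`is_active`.

    ``decimate`` keeps every n-th trace sample for the test (default 3, the
    energy operator's window length, so that tested samples come from
    disjoint pixel columns); the segment means reported in the result are
    computed from the same decimated samples.
    """
    if decimate < 1:
        raise ValueError(f"decimate must be >= 1, got {decimate}")
    results: dict[str, ActivationResult] = {}
    stride = np.zeros(len(trace.times), dtype=bool)
    stride[::decimate] = True
    base_mask = in_windows(trace.times, segments.baseline_windows) & stride
    stim_mask = in_windows(trace.times, segments.stim_windows) & stride
    if base_mask.sum() < 2 or stim_mask.sum() < 2:
        raise ValueError(
            "segments contain too few trace samples "
            f"(baseline {int(base_mask.sum())}, stimulation {int(stim_mask.sum())})"
        )
    for name in statistics:
        values = trace.statistic(name, smoothed=use_smoothed)
        a, b = values[base_mask], values[stim_mask]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            # degenerate (e.g. constant image): no evidence of activation
            results[name] = ActivationResult(
                statistic_name=name,
                mean_baseline=float(a.mean()),
                mean_stim=float(b.mean()),
                difference=float(b.mean() - a.mean()),
                ci95=(float(b.mean() - a.mean()), float(b.mean() - a.mean())),
                p_value=1.0,
                t=0.0,
                df=a.size + b.size - 2,
                active=False,
                alpha=alpha,
                n_baseline=a.size,
                n_stim=b.size,
            )
            continue
        tt = two_sample_t(a, b)
        p_one = tt.p_value / 2 if tt.difference > 0 else 1 - tt.p_value / 2
        results[name] = ActivationResult(
            statistic_name=name,
            mean_baseline=float(a.mean()),
            mean_stim=float(b.mean()),
            difference=tt.difference,
            ci95=tt.ci95,
            p_value=p_one,
            t=tt.t,
            df=tt.df,
            active=bool(p_one <= alpha and tt.difference > 0),
            alpha=alpha,
            n_baseline=a.size,
            n_stim=b.size,
        )
    return results


def is_active(
    results: dict[str, ActivationResult], criterion: str = "sd_tke"
) -> bool:
    """Overall activation decision.

    ``criterion='sd_tke'`` (default): the across-depth SD statistic must
    pass.  ``criterion='both'``: both SD and mean must pass.
    """
    if criterion == "both":
        return results["sd_tke"].active and results["mean_tke"].active
    if criterion in results:
        return results[criterion].active
    raise ValueError(f"unknown criterion {criterion!r}")


def detect_transient_peaks(
    trace: TKEOTrace,
    protocol: StimProtocol,
    prominence_factor: float = 20.0,
    guard_s: float = 0.5,
    max_width_s: float = 1.0,
) -> np.ndarray:
    """Times of narrow peaks of the smoothed mean-energy trace.

    Reported peaks must rise ``prominence_factor`` baseline SDs above their
    surroundings and be narrower than ``max_width_s`` at half prominence;
    the width bound separates the narrow on/off transients of an electrically
    elicited contraction from the broad elevation of the sustained plateau.
    Peaks within half a smoothing span of the trace ends are discarded (the
    shrinking edge windows make those samples effectively unsmoothed).  The
    peak list is descriptive and plays no part in the activation decision.
    """
    spec = segment_windows(protocol, guard_s)
    y = trace.mean_tke_smoothed
    base = y[in_windows(trace.times, spec.baseline_windows)]
    base_sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    if base_sd == 0:
        # flat baseline: any prominence at all is an event, but a perfectly
        # constant trace must yield no peaks
        base_sd = max(float(np.ptp(y)) * 1e-6, 1e-300)
    rate = 1.0
    if len(trace.times) > 1:
        rate = 1.0 / float(trace.times[1] - trace.times[0])
    idx, _ = signal.find_peaks(
        y,
        prominence=prominence_factor * base_sd,
        width=(None, max_width_s * rate),
        rel_height=0.5,
        distance=max(trace.span, 1),
    )
    margin = trace.span // 2
    idx = idx[(idx >= margin) & (idx < len(y) - margin)]
    return trace.times[idx]
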