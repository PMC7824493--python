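# Methods

## Overview

`mmode_tkeo` detects electrically elicited muscle contractions on M-mode
ultrasound. An M-mode scan is a depth-versus-time image: one scan line
recorded repeatedly, so each pixel row is a thin tissue layer (0.042 mm by
default) and each pixel column one acquisition instant (100 columns/s by
default). At rest the image shows static horizontal stripes — hyperechoic
connective-tissue interfaces over darker contractile tissue. A contraction
drags layers of differing echogenicity through the beam, changing the
brightness of a given row from column to column; that texture change, not
muscle thickness, is the detection signal.

The quantifier is the discrete Teager–Kaiser energy operator (TKEO)

    psi[x](n) = x(n)^2 − x(n−1) x(n+1),

applied independently to each pixel row as a time series. The operator
responds to both the amplitude and the frequency of local change (for a
sampled sinusoid `A cos(Ω n)` it returns the constant `A² sin² Ω`; for a
linear ramp of slope `a`, the constant `a²`; for a constant, zero). At each
instant the row-wise outputs are summarised by their mean and their sample
SD across depth. The across-depth SD — the heterogeneity of texture change
over layers — is the primary contraction indicator; the mean is reported
alongside it.

## Activation decision

For a stimulation sequence pause–surge–plateau–shrink–pause (defaults
6/2/12/2/6 s, 28 s total) the two pauses are the baseline segment and the
plateau the stimulation segment, each trimmed by a 0.5 s guard at phase
boundaries; surge and shrink are excluded entirely because they host the
narrow on/off energy transients, which are activation markers rather than
steady-state texture change. A pooled-variance two-sample Student t-test
compares the segments; the decision is `active` when the one-sided p-value
for an *increase* is at most α = 0.05 and the difference is positive. The
two-sided 95% CI for the difference is reported with every result.

Two calibration-critical choices:

* **The t-test consumes unsmoothed per-column statistics decimated to every
  third column.** Adjacent TKEO outputs share two of their three pixel
  columns, so neighbouring per-column statistics are serially dependent and
  an undecimated test is anti-conservative (measured false-positive rate
  0.135 at nominal 0.05). At stride 3 the operator windows are disjoint;
  under speckle-only conditions the tested samples are independent and the
  measured type-I rate is 0.057 over 600 null scans. Applying the test to
  the moving-average–smoothed trace would be far worse (span-31 smoothing
  makes nearly every null scan "significant").
* **The reported p is one-sided.** Activation is directional — only an
  increase of the energy statistics is evidence of contraction — and the
  one-sided rule is what makes the decision operate at its nominal α.

The smoothed trace (centred moving average whose span covers 0.3 s —
31 samples at 100 columns/s, always forced odd) is used for display and for
transient-peak finding only. At the edges the smoothing window shrinks
symmetrically, so constants are fixed points and length is preserved; the
TKEO itself drops its two undefined endpoint samples rather than zero-pad,
because padding would inject spurious energy exactly where transducer-motion
artifacts already concentrate.

Transient peaks of the smoothed mean-energy trace are located with a
prominence threshold (20 baseline SDs) plus a narrowness bound (≤ 1 s at
half prominence). The width bound separates the on/off twitches from the
broad plateau elevation, whose highest wiggle otherwise inherits the full
plateau prominence. Peaks within half a span of the trace ends are dropped
(those samples are effectively unsmoothed). The peak list is descriptive
and never enters the activation decision.

## Motor-threshold search

The sensory threshold (ST) is a patient report, not an imaging quantity; in
the simulator it is the latent ST rounded to the nearest mA. The search
starts at twice the ST. A level counts as active only when all 3 replicate
scans at that amplitude test active (a majority rule is available); with a
false-positive rate of ~0.05 per scan, the all-of-3 rule makes a spurious
level confirmation a ~10⁻⁴ event. If the start level is inactive the search
ascends in 1 mA steps and reports the first confirmed level; if active, it
descends and reports the smallest confirmed level visited. Absence of any
response up to `max_mA` is reported as an explicit "no motor response"
outcome (`found=False`), never as a number. With the all-or-none
contraction model the estimate is the first grid level at or above the
latent threshold, so the recovery error is bounded by one step.

## The synthetic-data generator

The generator emulates what the detection pipeline consumes, not acoustic
physics. Its components and the defaults that define the study conditions:

* **Resting texture** — Gaussian bright bands (five bands over the 20–40 mm
  analysis window, widths 0.4–0.55 mm, peak intensities 0.50–0.70 over a
  0.12 background) on the [0, 1] intensity scale.
* **Contraction** — all-or-none at the latent motor threshold (a 10% drop
  below threshold produces no response at all). At or above threshold the
  layers are displaced in depth by `gain × envelope(t)` where the envelope
  ramps 0→1 over the surge, holds 1 through the plateau and ramps back over
  the shrink; default gain 1.2 mm. Three additive refinements, all
  configurable and all off-able:
  * *plateau jitter*, a sinusoid of amplitude 0.2 × gain at 12 Hz standing
    in for sustained-contraction texture change. The frequency sits in the
    physiological fasciculation/tremor band and is chosen high enough that
    the jitter's energy (∝ sin² Ω) clears the speckle floor — at a few Hz
    the SD-of-TKEO indicator would have no power at realistic noise;
  * *onset/cessation twitches*, half-sine displacement bursts (1.0 × gain,
    0.12 s) at surge start and shrink end, reproducing the narrow mean-TKE
    peaks that simultaneous motor-unit recruitment and release produce;
  * *speckle*, additive zero-mean Gaussian noise (σ = 0.03 by default)
    clipped to [0, 1]. Multiplicative speckle statistics are out of scope.
* **Transducer-motion artifacts** — a Poisson number of smooth half-cosine
  global depth drifts at uniformly random times, deliberately uncorrelated
  with the stimulation envelope. Disabled by default and in the calibration
  experiments; they exist to let users probe artifact robustness.
* **Cohorts** — truncated-normal draws: MT 23.4 ± 4.94 mA on (13, 36),
  MT/ST ratio 2.69 ± 0.57 on (1.5, 4.5) (ST = MT/ratio, guaranteeing
  ST < MT), BMI 30.2 ± 6.7 on (16.7, 47.5), age 63.8 ± 14.1 on (25, 84).
  Subcutaneous-fat thickness has no tabulated reference statistics; 12 ±
  5 mm on (3, 30) is a realistic choice for an overweight adult cohort, and
  it is correlated 0.5 with BMI while both are independent of the
  thresholds (the observed threshold–anthropometrics correlations are near
  zero). Sampling is by rejection, so bounds hold exactly and everything is
  reproducible under a seed.

What the generator does **not** emulate: wave propagation, attenuation or
shadowing; multiplicative/Rayleigh speckle; depth-dependent contraction
(displacement is a global shift per column); electrode–tissue coupling; any
dependence of the contraction on pulse frequency (60 Hz and 120 Hz
protocols render identically by construction — the frequency-independence
test verifies the pipeline does not break this, not muscle physiology).
Passing tests therefore show the pipeline is correct and calibrated under
this texture model, not that it is validated on clinical scans.

## Cohort statistics

Descriptive rows report mean, sample SD (n−1), SE = SD/√n, range, biased
moment skewness `m₃/m₂^1.5` and raw kurtosis `m₄/m₂²` (3 for a normal), and
the Jarque–Bera p-value, with `JB = n/6 (S² + (K−3)²/4)`. The asymptotic p
is the χ²(2) tail `exp(−JB/2)`; because that is anti-conservative at a few
dozen samples, a seeded Monte-Carlo null (standard-normal samples of the
same size, default 10⁴ replicates) is available and neither method is
privileged. The MT/ST ratio is computed per patient and then averaged (mean
of ratios, not ratio of means). Regressions of MT and MT/ST on BMI and SAT
thickness are simple OLS with `R² = 1 − SS_res/SS_tot`; a constant response
is assigned R² = 0 by convention, and sexes are pooled.

## Numerical choices

* Rendering evaluates the depth profile through a lookup table at
  `mm_per_row/8` spacing with linear interpolation (error < 10⁻⁴ intensity,
  two orders below the speckle scale) — a ~5× speedup that leaves seeds
  bit-reproducible.
* Depth cropping keeps rows on the half-open interval `[z_min, z_max)` with
  0-based indices; intensities are normalised to [0, 1] by the image bit
  depth, and RGB inputs collapse by Rec. 601 luma. Absolute energy
  magnitudes therefore depend on this scale; only differences, ratios and
  decisions are scale-meaningful (the pipeline is covariant: scaling
  intensities by c scales all energy statistics by c²).
* Confidence-interval coverage for cohort means uses the Student t quantile
  (2.032 at n = 35), the correct nominal-95% multiplier at small n.
* Degenerate inputs fail loudly (zero variance, < 3 columns, empty
  segments, invalid truncation bounds), except that a perfectly constant
  trace yields an explicit "inactive, difference 0" result rather than an
  error — a flat image is a valid observation with no evidence of
  contraction.

## Experiment sizes

The calibration experiments use, as the package's own defaults: 200
unstimulated scans for the type-I rate (binomial 95% band 0.02–0.08 around
α = 0.05), 100 scans per gain level {0.2, 0.6, 1.2} mm for power
monotonicity, 20 virtual patients for threshold recovery, 5 patients × 2
frequencies for frequency agreement, 200 cohorts of 35 for CI coverage and
one 500-patient cohort for the flat-regression check. Scans in these
experiments cover the 20–40 mm analysis window (476 rows × 2800 columns).

## Known limitations

* The contraction/texture model is a stand-in: none of its parameters are
  calibrated against patient scans, and the absolute energy magnitudes of
  clinical exports depend on an intensity scale this package does not try
  to reproduce.
* Small-sample Jarque–Bera p-values depend on the calibration method;
  asymptotic and Monte-Carlo values can differ noticeably at n ≈ 35.
* The activation t-test assumes within-segment stationarity; slow drifts
  (e.g. transducer motion) inflate baseline energy and can mask true
  activation — a false-negative mechanism that guard margins do not remove.
* ST is taken as given; no attempt is made to infer sensation from imaging.
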