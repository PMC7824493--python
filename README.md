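# mmode-tkeo

Detection of electrically elicited muscle contractions on M-mode ultrasound,
via the Teager–Kaiser energy operator (TKEO).

During neuromuscular electrical stimulation (NMES), therapy is only
effective if the pulse amplitude actually triggers a contraction — and the
weakest amplitude that does so (the **motor threshold**, MT) varies from
patient to patient. A portable ultrasound probe held over the muscle in
M-mode records a depth-versus-time image in which a contraction appears as
a change of texture: tissue layers of different echogenicity cross the beam
and the brightness of each depth row starts fluctuating. This package turns
that observation into a quantitative, tested pipeline for physiotherapy
research: it decides *whether* a scan shows a contraction, searches the
motor threshold with the clinical staircase protocol, and summarises
cohorts — all exercised end-to-end on a built-in synthetic scan generator,
so no clinical recordings are required.

## Method

For each pixel row `x(n)` (a tissue layer observed over time) the discrete
Teager–Kaiser energy is

```
psi[x](n) = x(n)^2 − x(n−1) · x(n+1)
```

which is zero for constant signals, `a²` for a ramp of slope `a` and
`A² sin² Ω` for a sinusoid — i.e. it measures how strongly and how fast the
local signal changes. At each instant the row-wise outputs are reduced to
their mean and their sample SD across depth; the **SD of the TKEO outputs**
(texture-change heterogeneity over layers) is the contraction indicator.
A pooled two-sample t-test compares the stimulation plateau against the
pauses before and after stimulation (0.5 s guard margins; decision at
α = 0.05 for a one-sided increase, with a two-sided 95% CI), and the narrow
mean-energy peaks at stimulation on/off are reported as a descriptive
cross-check. The MT search starts at twice the sensory threshold, moves in
1 mA steps, and confirms a level only when all three replicate scans test
active.

## Worked example

`examples/` holds one short script per capability. Rendering a virtual
patient (latent MT 23.5 mA) stimulated at 24 mA and analysing the scan
(`examples/02_detect_activation.py`) prints:

```
supra-threshold (24 mA): active=True
  SD of TKE: 0.02667 -> 0.03389, difference +0.00722 (95% CI [0.00691, 0.00753]), p = 4.84e-216
  narrow mean-TKE peaks at t = [ 6.06 21.96] s (expected near stimulation on at 6 s / off at 22 s)
sub-threshold   ( 8 mA): active=False
  SD of TKE: 0.02684 -> 0.02685, difference +0.00001 (95% CI [-0.00019, 0.00022]), p = 0.444
```

The stimulated scan raises the across-depth energy SD by 27% with the on/off
transients exactly at the surge start (6 s) and shrink end (22 s); the
sub-threshold scan shows nothing. The staircase search
(`examples/03_motor_threshold_search.py`) then walks 18 → 24 mA and returns
MT = 24 mA — the smallest 1 mA level above the latent threshold:

```
   18.0 mA -> inactive
   ...
   23.0 mA -> inactive
   24.0 mA -> active
estimated MT: 24.0 mA (MT/ST ratio 2.67)
```

A thin CLI wraps the same functions for shell use:
`mmode-tkeo simulate-scan | simulate-cohort | analyze | find-mt | cohort`
(each run echoes its resolved configuration to a `*.config.json` for exact
reproduction).

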