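"""Decide whether a contraction occurred, on one stimulated and one null scan.

The decision compares the stimulation plateau against the pauses with a
pooled two-sample t-test on the SD-of-energy statistic (guard margins of
0.5 s exclude the surge/shrink transients), and the narrow on/off peaks of
the mean-energy trace are located as a descriptive cross-check.
"""

import numpy as np

from mmode_tkeo import (
    StimProtocol,
    VirtualPatient,
    detect_activation,
    detect_transient_peaks,
    is_active,
    render_scan,
    segment_windows,
    trace_from_scan,
)

protocol = StimProtocol(amplitude_mA=24.0)
patient = VirtualPatient(mt_true_mA=23.5, st_true_mA=9.0)
segments = segment_windows(protocol, guard_s=0.5)

for label, amplitude, seed in [("supra-threshold (24 mA)", 24.0, 2),
                               ("sub-threshold   ( 8 mA)", 8.0, 5)]:
    scan = render_scan(patient, protocol.with_amplitude(amplitude), seed=seed)
    trace = trace_from_scan(scan)
    results = detect_activation(trace, segments, alpha=0.05)
    res = results["sd_tke"]
    peaks = detect_transient_peaks(trace, protocol)
    print(f"{label}: active={is_active(results)}")
    print(f"  SD of TKE: {res.mean_baseline:.5f} -> {res.mean_stim:.5f}, "
          f"difference {res.difference:+.5f} "
          f"(95% CI [{res.ci95[0]:.5f}, {res.ci95[1]:.5f}]), p = {res.p_value:.3g}")
    print(f"  narrow mean-TKE peaks at t = {np.round(peaks, 2)} s "
          f"(expected near stimulation on at 6 s / off at 22 s)")

print("the decision operates at alpha = 0.05: about one unstimulated scan "
      "in twenty is still flagged, which the 3-replicate threshold search "
      "is designed to absorb")
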