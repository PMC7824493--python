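"""Estimate a virtual patient's motor threshold with the staircase protocol.

The search starts at twice the (reported) sensory threshold; each amplitude
level is confirmed only when all three replicate scans test active.  The
motor threshold is the smallest confirmed-active level.
"""

from mmode_tkeo import VirtualPatient, find_mt, make_simulated_stimulator

patient = VirtualPatient(mt_true_mA=23.5, st_true_mA=9.0, noise_sigma=0.02)
stimulate = make_simulated_stimulator(patient, seed=3)

result = find_mt(stimulate, st_mA=9.0, step_mA=1.0, replicates=3)

print(f"latent thresholds: ST {patient.st_true_mA} mA, MT {patient.mt_true_mA} mA")
print("search trajectory (level confirmed active only if all 3 scans active):")
for amplitude, active in result.trajectory:
    print(f"  {amplitude:5.1f} mA -> {'active' if active else 'inactive'}")
print(f"estimated MT: {result.mt_mA} mA (MT/ST ratio {result.ratio:.2f})")
print("the estimate is the smallest 1 mA level at or above the latent "
      "threshold - the staircase quantisation bounds the error by one step")
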