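"""Compute the left-knee range of motion over a simulated TUG trial.

The knee angle is derived purely from the thigh and shin orientation
quaternions: q_rel = q_thigh^-1 * q_shin, referenced to the seated pose at
t = 0, with the scalar angle 2*acos(|w|). It peaks near 90 degrees while
the subject rises from and returns to the chair, and stays near zero while
walking.
"""

import numpy as np

from tugseg import SimulationParams, rom_trace, simulate_tug

trial, truth = simulate_tug(SimulationParams(seed=1))
knee = rom_trace(trial, "knee_left")

print(f"{len(knee.angles_deg)} samples at {knee.rate_hz:.0f} Hz")
for seg in truth.segments:
    lo = int(seg.start_s * knee.rate_hz)
    hi = int(seg.end_s * knee.rate_hz)
    peak = np.max(knee.angles_deg[lo:hi])
    print(f"  {seg.name:<18} peak knee angle {peak:6.1f} deg")
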