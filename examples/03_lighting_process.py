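"""The cigarette-lighting renewal process behind the intake law.

With constant urge the waiting time to the next cigarette is
exponential; a linearly growing urge (lighting postponed, craving
building) shortens it. The reciprocal of the expected wait is the mean
intake rate Q.
"""

import numpy as np

from smokesim import (
    IntensityParams,
    expected_waiting_time,
    intake_rate,
    intake_to_cigarettes_per_hour,
    sample_lighting_times,
)

constant = IntensityParams(alpha=0.68, beta=0.0)
growing = IntensityParams(alpha=0.6, beta=0.013)

u = 0.5  # uncontrolled urge C - S of the calibrated moderate smoker
print(f"urge u = {u}:")
print(f"  constant urge: E[wait] = {expected_waiting_time(u, constant):.3f} h, "
      f"Q = {intake_rate(u, constant):.3f} mg/h "
      f"({intake_to_cigarettes_per_hour(intake_rate(u, constant), constant):.2f} cig/h)")
print(f"  growing urge:  E[wait] = {expected_waiting_time(u, growing):.3f} h, "
      f"Q = {intake_rate(u, growing):.3f} mg/h")

print("\nintake curves Q(u) [mg/h]:")
for uu in np.linspace(0.1, 0.6, 6):
    print(f"  u={uu:.1f}: constant {intake_rate(float(uu), constant):.3f}, "
          f"growing {intake_rate(float(uu), growing):.3f}")

rng = np.random.default_rng(1)
events = sample_lighting_times(u, constant, horizon=160.0, rng=rng)
print(f"\nsampled {events.size} lighting events over 10 days (16 h each): "
      f"{events.size / 10:.1f} per day vs expected {0.34 * 16:.1f} "
      "(rate alpha*u in intake units; x1/0.425 for cigarettes)")
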