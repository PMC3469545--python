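"""How the one-year success rate depends on the control-noise amplitude.

The default calibration pins the stationary sd of the control at
1/75 = 0.0133 around the set-point 0.05.  Relapse after a successful
therapy requires the control to dip below ~0, a 3.8-sigma excursion at
that amplitude — so almost nobody relapses within the post-therapy
year and the abrupt 30-day scheme succeeds essentially always.  Only
when the control sd grows to ~0.04-0.05 (relapse a ~1-sigma event)
do one-year success rates fall to the few-tens-of-percent range seen
in cessation practice.
"""

import math

from smokesim import ControlParams, TherapyScheme, success_rate

Q_DRIFT = 0.011935  # default reversion rate (1/84 h)
scheme = TherapyScheme.abrupt(30)

print("control sd   success of abrupt 30-day scheme (50 runs)")
for sd in (1 / 75.0, 0.03, 0.046, 0.06):
    control = ControlParams(S0=0.05, epsilon=sd * math.sqrt(2 * Q_DRIFT), q=Q_DRIFT)
    k, n = success_rate(scheme, control=control, n_runs=50, base_seed=37)
    print(f"  {sd:6.4f}     {k:2d}/{n}")
print("(same drift time scale throughout; only the diffusion amplitude varies)")
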