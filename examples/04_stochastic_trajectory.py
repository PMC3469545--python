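"""A long stochastic realization of the coupled system.

The control S mean-reverts to 0.05 with stationary sd 1/75; at that
amplitude its excursions almost never cross the folds at 0 and 0.086,
so a steady smoker stays a steady smoker.  A few-fold larger, slower
control noise produces spontaneous quitting and relapse.
"""

import math

import numpy as np

from smokesim import ControlParams, State, simulate_sde, write_results

start = State(N=0.6795, C=0.4347, S=0.05)

traj = simulate_sde(start, duration_h=1000 * 16.0, dt=0.1, seed=42)
print("default control noise (stationary sd = 1/75 = 0.0133):")
print(f"  S: mean {traj.S.mean():.4f}, sd {traj.S.std():.4f}, "
      f"min {traj.S.min():.4f}, max {traj.S.max():.4f}")
print(f"  intake Q: mean {traj.Q.mean():.3f} mg/h "
      f"(steady smoking throughout; clamped steps: {traj.metadata['n_clamped']})")

q = 1.03e-3  # slower reversion (~2 months) ...
loud = ControlParams(S0=0.05, epsilon=0.046 * math.sqrt(2 * q), q=q)  # ... sd 0.046
traj2 = simulate_sde(start, duration_h=1000 * 16.0, dt=0.1, seed=42, control=loud)
frac_abstinent = float(np.mean(traj2.Q < 0.013))
print("\nenlarged control noise (sd 0.046, ~2-month reversion):")
print(f"  S range [{traj2.S.min():.3f}, {traj2.S.max():.3f}]; "
      f"fraction of time abstinent: {frac_abstinent:.2f}")
print("  (negative control = peer pressure to smoke; relapse follows)")

csv_path, _ = write_results(traj2, "scratch_trajectory.csv")
print(f"wrote {csv_path}")
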