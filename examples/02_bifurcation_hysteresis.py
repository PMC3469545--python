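"""Sweep the control S and export the equilibrium branches.

Inside the bistable window both steady smoking and abstinence are
attractors; slowly raising and lowering S therefore traces a hysteresis
loop — quitting at the upper fold, relapsing at the lower one.
"""

import numpy as np

from smokesim import bifurcation_diagram, bistable_interval, ModelParams, write_results

params = ModelParams()
low, high = bistable_interval(params)
print(f"bistable control interval: [{low:.3f}, {high:.4f}]")
print("  below 0: only steady smoking;  above the fold: only abstinence")

diagram = bifurcation_diagram(params, np.linspace(-0.05, 0.15, 201))
csv_path, sidecar = write_results(diagram, "scratch_bifurcation.csv")
frame = diagram.to_frame()
n_bistable = (frame.groupby("S").size() == 3).sum()
print(f"wrote {csv_path} ({len(frame)} branch points; "
      f"{n_bistable} grid values with 3 equilibria)")
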