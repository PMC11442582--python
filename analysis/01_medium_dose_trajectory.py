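"""Medium-dose injury simulation.

Integrates the model for the Medium initial senescence (T_in = 1.4, all
rates 1), verifies solver convergence, and tabulates the transient: every
responder population rises to an interior peak and returns to homeostasis,
while the senescent pool decays monotonically (10% clearance at t ~ 1.55).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from senoliv import (
    InitialCondition,
    ModelParameters,
    check_convergence,
    clearance_time,
    peak_summary,
    simulate,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = ModelParameters()
init = InitialCondition(T_in=1.4)
traj = simulate(params, init)

# resample onto an even grid over the active transient for a compact table
t_grid = np.linspace(0.0, 30.0, 301)
states = traj.at(t_grid)
tidy = pd.DataFrame(states, columns=["T", "M1", "M2", "E", "C", "F"]).assign(time=t_grid)
tidy.melt(id_vars="time", var_name="variable", value_name="value").to_csv(
    OUT / "medium_dose_trajectory.csv", index=False
)
peaks = peak_summary(traj)
peaks.to_csv(OUT / "medium_dose_peaks.csv", index=False)

tc = clearance_time(traj)
gap = check_convergence(params, init)

print(f"outcome: {traj.outcome} (horizon t_end = {traj.config.t_end})")
print(f"senescent-cell 10% clearance time t_c = {tc:.4f}")
print(f"tolerance-refinement convergence gap = {gap:.2e}")
print(peaks.to_string(index=False))
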