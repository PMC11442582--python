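# senoliv

Dynamics of acute senescence-driven liver injury: a six-variable
mass-action ODE model of the injured liver niche, with the analyses a
regeneration biologist or modeller needs around it — trajectory
simulation, steady-state and linear stability analysis, critical-dose
bisection, clearance-time parameter studies, a synthetic in vivo-style
fold-change dataset generator, and a qualitative validation harness.

## The problem

Acute liver injury can be induced experimentally by a controlled dose of
hepatocyte senescence.  The injured niche then runs an inflammatory phase
(M1 macrophage recruitment, endothelial activation, myofibroblast
activation, collagen-I deposition) followed by a regenerative phase (an
M1→M2 phenotype switch, senescent-cell clearance, ECM breakdown) — or, if
the initial senescent load is too high, inflammation feeds on itself and
never resolves.  The model captures that competition with six coupled
ODEs for deviations from homeostasis:

    dT/dt  = -K_T·M2·T - D·T                          (senescent cells)
    dM1/dt = B₁·T + E - S·M1 - D·M1                   (pro-inflammatory macrophages)
    dM2/dt = B₂·T + S·M1 - D·M2                       (pro-regenerative macrophages)
    dE/dt  = B_E·(1+E)·M1 - D·E                       (activated endothelium)
    dC/dt  = B_C·F - K_C·M2·C - D·C                   (excess ECM / collagen-I)
    dF/dt  = B_F·M1 - K_F·M2·F - D·F                  (activated myofibroblasts)

with switch term S = G/((C+1)(F+1)) and initial condition
(T_in, 0, 0, 0, 0, 0).  All rates default to 1 (dimensionless, time
normalised on the endothelial recruitment of macrophages).  Homeostasis
(the origin) is stable exactly when the phenotype-switch rate beats
endothelial activation, G > B_E − 1; inside that regime a critical dose
T_in\* separates full resolution from runaway inflammation.

## Worked example

```python
from senoliv import (ModelParameters, InitialCondition, simulate,
                     critical_senescence, clearance_time)

params = ModelParameters()                 # all rates 1
traj = simulate(params, InitialCondition(T_in=1.4))
print(traj.outcome)                        # resolved
print(f"{clearance_time(traj):.4f}")       # 1.5509  (time for T to hit 10% of T_in)

res = critical_senescence(params)
print(f"{res.tin_star:.4f}")               # 2.3312  (critical dose, bracket ±1e-3)
```

The medium dose (T_in = 1.4) resolves: every responder population rises
to an interior peak (M1 peaks at 0.356 at t ≈ 0.76, M2 at 0.611, E at
0.323, C at 0.129, F at 0.184) and returns to homeostasis, while the
senescent pool decays monotonically, reaching 10% of the dose at
t_c ≈ 1.55.  The critical dose for the default rates is T_in\* ≈ 2.331:
doses 0.6, 1.4, 2.2 resolve; 2.7 triggers runaway inflammation (the
integrator stops at the blow-up bound).  Increasing the switch rate G
raises the tolerated dose; increasing endothelial activation B_E lowers
it; increasing M2 recruitment B₂ or M2-mediated removal K_T shortens the
clearance time monotonically.

The same machinery drives the numbered analyses:

```bash
python analysis/01_medium_dose_trajectory.py      # transient + convergence check
python analysis/02_steady_states_and_stability.py # regimes on a (G, B_E) grid
python analysis/03_critical_threshold.py          # T_in* bisection + dose ladder
python analysis/04_parameter_sweeps.py            # threshold surface, t_c sweeps (~3 min)
python analysis/05_synthetic_cohort_validation.py # synthetic cohort + round trip
```

Each driver prints what it found and writes tidy tables under
`results/`.  The synthetic cohort (script 05) emulates the study design
the model was built against — fold-change readouts for twelve markers
(p21, CD80/CD86, CD206/CD163, VCAM-1⁺ERG⁺, ICAM-1, ACKR3, α-SMA, PDGFRB,
COL1A1/2) at days 3/7/14, N = 4 animals per dose group
(control/mild/moderate/severe), log-normal noise — and the validation
harness confirms the round trip: transient rise, day-14 resolution, dose
ordering and model–data co-direction all pass (e.g. CD80 day-3 group
means ≈ 8.6 / 32.9 / 117 for mild/moderate/severe, seed 0).

A `senoliv` CLI exposes the same operations
(`senoliv simulate|steady-states|critical|surface|clearance-sweep|dose-response|generate-data|validate`),
writing its resolved configuration next to every output for
reproducibility.

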