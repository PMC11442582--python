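# Methods

## Model

`senoliv` implements a well-mixed, mass-action ODE model of acute
senescence-driven liver injury.  Six state variables describe deviations
from homeostasis: the senescent hepatocyte load `T`, pro-inflammatory and
pro-regenerative macrophages `M1`, `M2`, activated endothelial cells `E`,
excess collagen-I ECM `C` and activated myofibroblasts `F`:

    dT/dt  = -K_T*M2*T - D*T
    dM1/dt = B_1*T + E - S*M1 - D*M1        S = G / ((C+1)(F+1))
    dM2/dt = B_2*T + S*M1 - D*M2
    dE/dt  = B_E*(1+E)*M1 - D*E
    dC/dt  = B_C*F - K_C*M2*C - D*C
    dF/dt  = B_F*M1 - K_F*M2*F - D*F

Assumptions: populations are spatially well mixed; every species shares
one death/deactivation rate `D`; senescent cells (whether primary or
paracrine-induced — the model pools them) recruit both macrophage
phenotypes; activated endothelium recruits M1 (with unit rate, because
time is normalised on exactly that recruitment timescale) and is itself
activated and expanded by M1; the M1→M2 phenotype switch at rate `G` is
inhibited by accumulated ECM and myofibroblasts through the divisor
`(C+1)(F+1)`; M2 clears senescent cells, degrades excess ECM and
deactivates myofibroblasts.  Injury is a senescent bolus at time zero:
`(T, M1, M2, E, C, F)(0) = (T_in, 0, 0, 0, 0, 0)`.

All eleven parameters (ten rates plus the dose `T_in`) are nonnegative and
default to 1, the reference point for every analysis here.  The
nonnegative orthant is forward-invariant (each boundary face has inward or
tangent flow), and `dT/dt <= -D*T` gives the uniform bound
`T(t) <= T_in*exp(-D*t)`: the senescent pool always clears; what can fail
to resolve is the inflammatory response it triggers.

## Steady states, stability and regime

With `T = 0`, the fixed-point system reduces to a single scalar equation:
the endothelial balance gives `E = B_E*M1/(D - B_E*M1)` for
`M1 < D/B_E`, the M1 balance fixes the switch level `S(M1)`, the M2, F
and C balances then follow sequentially, and self-consistency
`S*(C+1)*(F+1) = G` closes the loop.  `find_steady_states` scans the
admissible `M1` interval (512 points) for sign changes and refines with
Brent's method; a reported state must have max |rhs| < 1e-10.  This
replaces a closed-form solution with a numerically certified one.

Homeostasis is always a steady state.  Whenever `G > B_E - 1` (at
`D = 1`) it is linearly stable and an all-positive unstable state exists
as well — the saddle whose stable manifold separates resolving from
runaway initial conditions.  When `G < B_E - 1` only unstable homeostasis
remains and no positive dose can resolve.  `regime()` implements the
`G > B_E - 1` rule literally (strict; the boundary is classified
no-resolution with a warning).  For general `D` the trivial-state
eigenvalue analysis gives `D*(G + D) > B_E`, which reduces to the rule at
`D = 1`; the package asserts the stated rule only at `D = 1` and the
eigenvalue route is always available for other `D` (the `D = 0.5` cases in
the tests are classified by eigenvalues, not by the rule).  Eigenvalues
with `|Re| < 1e-9` count as marginal.

## Numerics

* Integrator: adaptive explicit RK45 (`scipy.integrate.solve_ivp`),
  `rtol = 1e-8`, `atol = 1e-10` — deliberately strict because bisection on
  a classifier needs reliable outcomes.  A terminal event stops
  integration when any component reaches the blow-up bound `1e6`;
  supercritical runs exhibit finite-time-like blow-up (the `B_E*(1+E)*M1`
  term), so they terminate within a few time units.
* Outcome classification: `resolved` iff every component's magnitude at
  `t_end` (default 500) is below `eps_res = 1e-3` (homeostasis is exactly
  0, so a strictly positive band is needed for finite-time
  classification); `unresolved` iff the blow-up bound was hit or every
  non-T component is still growing over the last tenth of the horizon
  (T always decays, so it is excluded from the growth test); otherwise
  `undetermined`, and the caller extends the horizon.  Near the threshold
  trajectories dwell at the saddle and resolution times diverge; the
  explicit `undetermined` outcome plus horizon-doubling (cap 8000) makes
  this visible rather than guessed.
* Critical dose: bisection on `T_in` to tolerance `1e-3`, starting from
  `[0.1, 10]` with geometric expansion until the endpoints classify
  (resolved, unresolved).  The result carries its certificate bracket.
  A point that is still `undetermined` at the horizon cap is treated as
  unresolved (conservative) and counted.
* Clearance time `t_c`: first down-crossing of `0.1*T_in` (the fraction is
  exposed), bracketed on stored points and refined with Brent's method on
  the solver's dense output — the closed-form check `t_c = ln(10)/D` at
  `K_T = 0` then agrees to ~1e-9.
* Peaks are refined by a local quadratic fit around the discrete argmax;
  T's peak is pinned to `(T_in, 0)`.
* Convergence is certified by re-solving at tolerances/10 and taking the
  sup-norm difference at shared times (`check_convergence`), ~1e-9 for the
  medium dose.

Default sweep grids: 15 log-spaced points in [0.2, 8] for the `(G, B_E)`
threshold surface (inadmissible cells are labelled, never computed) and 12
log-spaced points in [0.25, 8] for the `B_2`/`K_T` clearance sweeps at
doses {0.6, 1.4, 2.2} — small enough to run on a laptop in minutes,
dense enough to resolve the monotone trends.  Iso-threshold contours are
extracted with marching squares (contourpy) on the masked grid.

## Synthetic cohort generator

The generator emulates the statistical shape of the study's readouts so
the validation harness is testable without animal data: dose groups
control/mild/moderate/severe (`T_in` = 0, 0.6, 1.4, 2.2), days 3/7/14,
N = 4 (3–5 supported) animals per group and day, twelve markers mapped
linearly onto model variables (`fold change = 1 + gain * variable`,
baseline 1 = healthy-control mean): p21→T, CD80/CD86→M1, CD206/CD163→M2,
VCAM1⁺ERG⁺/ICAM1/ACKR3→E, αSMA/PDGFRB→F, COL1A1/COL1A2→C.  Supercritical
groups are rejected — the emulated study design never doses above
threshold.

**Day mapping.**  The model's unit of time is the macrophage-recruitment
timescale and carries no reported conversion to days, so the mapping
`day = s * t` is a calibration choice.  Two desiderata compete: putting
the M1 peak at day 3 (where CD80 peaks in tissue) and having all groups
back at control levels by day 14.  They cannot both hold: the slowest
decay eigenvalue at homeostasis is `(-3+sqrt(5))/2 ≈ -0.38`, so eleven
days of decay after a day-3 peak would leave ~18% of the peak — far from
baseline.  Because every day-14 readout in the emulated study is at
control level, and the validation harness keys on that, the resolution
side wins: `s` is set so the largest default dose falls an order of
magnitude inside the resolution band exactly at day 14
(`s ≈ 0.386` days/unit for the default parameters).  The responder peaks
then map to ~day 1 and the day-3/7/14 samples sit on the decay flank; the
transient rise-and-return shape is preserved, the peak day is not.

**Gains.**  The p21 gain is anchored so the noiseless moderate day-7
value is exactly 114.6 and the CD80 gain so moderate day 3 is 30-fold;
with these two anchors the generator reproduces the observed ~10/30/100
mild/moderate/severe CD80 tiering at day 3 without further tuning.  The
remaining markers use modest day-3 anchors (2.5–8-fold), matching the
order of magnitude of their transcript changes.  Two consequences of the
linear map + fast `T` decay are accepted and documented rather than
patched: synthetic p21 is enormous at day 3 (the model's senescent pool
decays at rate ≥ D per time unit, far faster than the responders), and at
the sampled days the senescent pool is *lower* in higher-dose groups —
more M2 means faster clearance — so p21 dose ordering at D3–D14 is
clearance-dominated and inverted relative to the responders.

**Noise.**  Per-animal observations are log-normal with median equal to
the noiseless value (fold changes are positive and right-skewed).  The
p21 coefficient of variation (0.55) is back-calculated from the reported
moderate day-7 dispersion (SEM/mean = 31.53/114.6 at N = 4); other
markers default to CV = 0.3.  A single seed drives the whole cohort;
identical seeds give byte-identical datasets.

**What is not emulated:** the qPCR ΔΔCt pipeline (fold changes are drawn
directly; Ct-level noise adds parameters with no downstream effect),
the AAV-dose→recombination→`T_in` mapping, %FOV vs cell-count
distinctions (histology markers share the linear observation model with
separate gains), inter-animal correlation across days (each observation
is independent), and any marker-specific kinetic delay (all markers of a
variable move together).  Passing round-trip tests therefore show that
the harness detects the model's qualitative signatures under realistic
sampling noise — not that the model fits real mice.

## Validation harness

`qualitative_checks` turns "the model qualitatively captures the data"
into five deterministic checks on group summaries (mean, SEM, N) against
the model's noiseless curves, with a pooled healthy-control band:

1. **transient** — responder markers exceed `control mean + 2*SEM` at a
   non-final day, evaluated only where the model itself predicts a ≥2-fold
   effect (mild-dose markers are expected to stay near control, as
   observed in the study).
2. **resolution** — final-day means are back at control.  Judged on the
   log scale (delta method) and a failure requires *both* ≥1.75-fold
   deviation *and* ≥4 combined standard errors.  A plain ±k·SEM band at
   N = 3–5 with estimated SEMs false-fails ~25% of clean cohorts; the
   equivalence-style rule had 0 false failures in 100 seeds at CV 0.3,
   N = 5, while still failing constructed non-resolving datasets by a wide
   margin.
3. **senescence decline** — p21 group means never increase after their
   peak day (5% slack).
4. **dose ordering** — severe ≥ moderate ≥ mild at the model's peak day,
   with 5% relative slack, for responder markers (the senescent pool's
   ordering at the sampled days is clearance-dominated, see above).
5. **co-direction** — the sign of the day-3→day-7 change agrees between
   model and data wherever the model predicts a clear trend (≥0.25 fold
   units); insignificant data changes (≤2 SE) are not failed on sign.

Missing groups or days make individual checks "not evaluable" rather than
raising.  All thresholds live in `CompareConfig`.  The band/guard
constants are this package's operationalisation of a visual judgement —
there is no reported quantitative criterion to inherit — and were set for
the N = 3–5, CV 0.2–0.3 regime the generator emulates.

## Problem sizes

The bundled analyses and test suite run on one CPU in a few minutes:
one threshold bisection is 15–25 ODE solves (~1 s); the regime grid is
5×5; acceptance-level monotonicity sweeps use 12-point grids; the
threshold surface driver uses the full 15×15 grid (~3 min); the
round-trip robustness test amortises the four group simulations across
100 noise seeds.

## Known limitations

* The `G > B_E - 1` regime rule is asserted only at `D = 1`; for other
  `D` use the eigenvalue route.
* The non-trivial steady state is found numerically (certified by
  residual), not in closed form.
* The threshold surface at large `G` grows steeply (tolerated doses in the
  thousands); bracket expansion handles it but the bisection cost grows
  logarithmically with the threshold.
* Supercritical trajectories end at the blow-up bound; quantities defined
  along them (e.g. clearance at very large doses) can be truncated, and
  such cells are flagged in sweep tables.
* No spatial structure, no stochasticity, no parameter fitting to data —
  the model is a qualitative mechanism probe, and the synthetic cohorts
  inherit that status.
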