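"""Trajectory integration, outcome classification and trajectory summaries."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import STATE_VARS, InitialCondition, ModelParameters, _jacobian, _rhs

__all__ = [
    "SolverConfig",
    "Trajectory",
    "SolverFailure",
    "HorizonTooShortError",
    "simulate",
    "classify_outcome",
    "clearance_time",
    "peak_summary",
    "check_convergence",
]

RESOLVED = "resolved"
UNRESOLVED = "unresolved"
UNDETERMINED = "undetermined"


class SolverFailure(RuntimeError):
    """Adaptive integration failed (step-size underflow)."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time t={last_time:g})")
        self.last_time = last_time


class HorizonTooShortError(RuntimeError):
    """A requested trajectory feature lies beyond the integrated horizon."""


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive RK45 settings plus the outcome-classification knobs.

    ``blowup`` is the state magnitude at which integration stops early and
    the run is flagged divergent; ``eps_res`` is the band around homeostasis
    within which a variable counts as resolved.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    t_end: float = 500.0
    max_step: float = np.inf
    blowup: float = 1e6
    eps_res: float = 1e-3

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.blowup <= self.eps_res:
            raise ValueError("blow-up bound must exceed the resolution band eps_res")

    def refined(self, factor: float = 10.0) -> "SolverConfig":
        return replace(self, rtol=self.rtol / factor, atol=self.atol / factor)


@dataclass
class Trajectory:
    """Solution of one injury simulation at the solver's accepted steps."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 6), columns ordered as STATE_VARS
    params: ModelParameters
    init: InitialCondition
    config: SolverConfig
    outcome: str
    diagnostics: dict = field(default_factory=dict)
    _dense: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.shape != (self.t.size, 6):
            raise ValueError("trajectory arrays must be (n,) times and (n, 6) states")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trajectory states must be finite")

    @property
    def blowup_hit(self) -> bool:
        return bool(self.diagnostics.get("blowup_hit", False))

    def at(self, t):
        """State at arbitrary time(s) within the horizon (dense output)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t[0]) or np.any(t > self.t[-1]):
            raise HorizonTooShortError(
                f"requested time outside integrated range [0, {self.t[-1]:g}]"
            )
        if self._dense is not None:
            out = np.atleast_2d(np.asarray(self._dense(t)).T)
        else:
            out = np.column_stack(
                [np.interp(t, self.t, self.y[:, j]) for j in range(6)]
            )
        return out[0] if t.ndim == 0 else out

    def component(self, name: str) -> np.ndarray:
        return self.y[:, STATE_VARS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: columns time, variable, value."""
        n = self.t.size
        return pd.DataFrame(
            {
                "time": np.repeat(self.t, 6),
                "variable": np.tile(np.asarray(STATE_VARS), n),
                "value": self.y.ravel(),
            }
        )


def simulate(
    params: ModelParameters,
    init: InitialCondition,
    cfg: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the model with adaptive RK45 and classify the outcome.

    Integration halts early (outcome ``unresolved``) when any component
    exceeds the blow-up bound, so supercritical doses terminate quickly
    instead of overflowing.
    """
    cfg = cfg or SolverConfig()
    y0 = init.as_array()

    def fun(t, y):
        return _rhs(y, params)

    def blowup_event(t, y):
        return cfg.blowup - np.max(np.abs(y))

    blowup_event.terminal = True
    blowup_event.direction = -1

    sol = solve_ivp(
        fun,
        (0.0, cfg.t_end),
        y0,
        method="RK45",
        rtol=cfg.rtol,
        atol=cfg.atol,
        max_step=cfg.max_step,
        events=blowup_event,
        dense_output=True,
    )
    if sol.status == -1:
        raise SolverFailure(sol.message, last_time=float(sol.t[-1]) if sol.t.size else 0.0)

    blowup_hit = sol.status == 1
    t, y = sol.t, sol.y.T
    if blowup_hit and sol.t_events[0].size:
        te = float(sol.t_events[0][0])
        if te > t[-1]:
            t = np.append(t, te)
            y = np.vstack([y, sol.y_events[0][0]])

    traj = Trajectory(
        t=t,
        y=y,
        params=params,
        init=init,
        config=cfg,
        outcome=UNDETERMINED,
        diagnostics={
            "nfev": int(sol.nfev),
            "steps": int(sol.t.size - 1),
            "status": int(sol.status),
            "blowup_hit": blowup_hit,
        },
        _dense=sol.sol,
    )
    traj.outcome = classify_outcome(traj, cfg.eps_res)
    return traj


def classify_outcome(traj: Trajectory, eps_res: float | None = None) -> str:
    """Long-time outcome: ``resolved``, ``unresolved`` or ``undetermined``.

    Resolved means every component is inside the homeostasis band at the end
    of the horizon.  Unresolved means the blow-up bound was hit, or every
    component other than T (which always decays exponentially) is still
    growing over the last tenth of the horizon — the uncontrolled
    inflammation outcome in which all populations except the senescent cells
    keep increasing.  Anything else is undetermined: extend the horizon.
    """
    eps = traj.config.eps_res if eps_res is None else eps_res
    if traj.blowup_hit:
        return UNRESOLVED
    final = traj.y[-1]
    if np.max(np.abs(final)) < eps:
        return RESOLVED
    earlier = traj.at(0.9 * traj.t[-1])
    if np.all(final[1:] > earlier[1:]):
        return UNRESOLVED
    return UNDETERMINED


def clearance_time(traj: Trajectory, fraction: float = 0.10) -> float:
    """Time for the senescent population to fall to ``fraction`` of T_in.

    T is strictly decreasing (dT/dt <= -D*T), so the first stored
    down-crossing is the only one.  The crossing is bracketed by stored
    points and refined on the solver's continuous extension (falling back
    to linear interpolation when no dense output is attached).
    """
    T0 = traj.y[0, 0]
    if T0 <= 0:
        raise ValueError("clearance time requires T_in > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    target = fraction * T0
    T = traj.y[:, 0]
    below = np.nonzero(T <= target)[0]
    if below.size == 0:
        raise HorizonTooShortError(
            f"T never reached {fraction:.0%} of T_in within t_end={traj.t[-1]:g}"
        )
    i = int(below[0])
    if i == 0:
        return float(traj.t[0])
    t0, t1 = float(traj.t[i - 1]), float(traj.t[i])
    if traj._dense is not None:
        from scipy.optimize import brentq

        return float(brentq(lambda t: traj.at(t)[0] - target, t0, t1, xtol=1e-12))
    v0, v1 = T[i - 1], T[i]
    return float(t0 + (v0 - target) / (v0 - v1) * (t1 - t0))


def _quadratic_refine(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete argmax by fitting a parabola to its neighbours."""
    if i == 0 or i == len(t) - 1:
        return float(v[i]), float(t[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    v0, v1, v2 = v[i - 1], v[i], v[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (v1 - v0) + t1 * (v0 - v2) + t0 * (v2 - v1)) / denom
    b = (t2**2 * (v0 - v1) + t1**2 * (v2 - v0) + t0**2 * (v1 - v2)) / denom
    if a >= 0:  # degenerate (flat or non-concave): keep the grid point
        return float(v1), float(t1)
    tp = -b / (2 * a)
    if not t0 <= tp <= t2:
        return float(v1), float(t1)
    c = v1 - a * t1**2 - b * t1
    return float(a * tp**2 + b * tp + c), float(tp)


def peak_summary(traj: Trajectory) -> pd.DataFrame:
    """Per-variable peak value and peak time (quadratically refined).

    T decays monotonically, so its peak is pinned to (T_in, 0).
    """
    rows = []
    for j, name in enumerate(STATE_VARS):
        if name == "T":
            rows.append({"variable": "T", "peak": float(traj.y[0, 0]), "peak_time": 0.0})
            continue
        v = traj.y[:, j]
        i = int(np.argmax(v))
        peak, tp = _quadratic_refine(traj.t, v, i)
        rows.append({"variable": name, "peak": peak, "peak_time": tp})
    return pd.DataFrame(rows)


def check_convergence(
    params: ModelParameters,
    init: InitialCondition,
    cfg: SolverConfig | None = None,
    factor: float = 10.0,
) -> float:
    """Max-norm gap between the solution and a re-solve at tighter tolerance.

    Returns sup over the base run's stored times of the componentwise
    absolute difference against a run with rtol and atol divided by
    ``factor``; small values certify solver convergence.
    """
    cfg = cfg or SolverConfig()
    base = simulate(params, init, cfg)
    fine = simulate(params, init, cfg.refined(factor))
    t_shared = base.t[base.t <= fine.t[-1]]
    return float(np.max(np.abs(base.at(t_shared) - fine.at(t_shared))))
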