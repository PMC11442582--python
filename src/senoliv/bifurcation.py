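"""Critical-dose bisection and parameter studies.

The central quantity is the critical initial senescence T_in*: the largest
senescent bolus the system can resolve.  Below it every population returns
to homeostasis; above it endothelial activation feeds macrophage
recruitment faster than the phenotype switch can drain it and inflammation
runs away.  T_in* is found by bisection on the long-time outcome
classifier, which is monotone in T_in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import InitialCondition, ModelParameters
from .simulate import (
    RESOLVED,
    UNDETERMINED,
    UNRESOLVED,
    HorizonTooShortError,
    SolverConfig,
    Trajectory,
    clearance_time,
    peak_summary,
    simulate,
)
from .steady_state import NO_RESOLUTION, regime

__all__ = [
    "ThresholdResult",
    "NoThresholdError",
    "BracketError",
    "critical_senescence",
    "tin_star_surface",
    "contour_polylines",
    "clearance_sweep",
    "dose_response",
]

#: Low / Medium / High dose analogues of the study severity tiers.
DOSE_LEVELS = (0.6, 1.4, 2.2)


class NoThresholdError(RuntimeError):
    """No finite threshold exists: the trivial state is unstable."""


class BracketError(RuntimeError):
    """Bracket expansion failed to enclose the threshold."""


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection estimate of T_in* with its certificate bracket."""

    tin_star: float
    lo: float  # classifies resolved
    hi: float  # classifies unresolved
    tol: float
    config: SolverConfig
    n_classifications: int
    n_undetermined: int

    def __post_init__(self) -> None:
        if not (self.lo < self.tin_star <= self.hi):
            raise ValueError("threshold estimate must lie in (lo, hi]")


def _classify_dose(
    T_in: float, params: ModelParameters, cfg: SolverConfig, t_end_cap: float
) -> tuple[str, int]:
    """Classify one dose, doubling the horizon while it stays undetermined."""
    n_undet = 0
    local = cfg
    while True:
        out = simulate(params, InitialCondition(T_in=T_in), local).outcome
        if out != UNDETERMINED:
            return out, n_undet
        n_undet += 1
        if local.t_end * 2 > t_end_cap:
            # Horizon exhausted while still drifting: treat as unresolved so
            # bisection stays conservative, but count it for diagnostics.
            return UNRESOLVED, n_undet
        local = replace(local, t_end=local.t_end * 2)


def critical_senescence(
    params: ModelParameters,
    bracket: tuple[float, float] = (0.1, 10.0),
    tol: float = 1e-3,
    cfg: SolverConfig | None = None,
    max_expand: int = 10,
    t_end_cap: float = 8000.0,
) -> ThresholdResult:
    """Bisection for the critical initial senescence T_in*.

    The initial bracket is expanded geometrically (lo halved, hi doubled,
    up to ``max_expand`` times each) until it classifies as
    (resolved, unresolved); midpoints that come back undetermined get a
    doubled horizon up to ``t_end_cap`` before being re-classified.
    """
    if regime(params) == NO_RESOLUTION:
        raise NoThresholdError(
            "no finite threshold: trivial state unstable (G <= B_E - 1)"
        )
    cfg = cfg or SolverConfig()
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")

    n_class = 0
    n_undet = 0

    def classify(x: float) -> str:
        nonlocal n_class, n_undet
        out, nu = _classify_dose(x, params, cfg, t_end_cap)
        n_class += 1
        n_undet += nu
        return out

    for _ in range(max_expand + 1):
        if classify(lo) == RESOLVED:
            break
        lo /= 2.0
    else:
        raise BracketError(f"lower bracket never classified resolved (last lo={lo:g})")
    for _ in range(max_expand + 1):
        if classify(hi) == UNRESOLVED:
            break
        hi *= 2.0
    else:
        raise BracketError(f"upper bracket never classified unresolved (last hi={hi:g})")

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify(mid) == RESOLVED:
            lo = mid
        else:
            hi = mid

    return ThresholdResult(
        tin_star=0.5 * (lo + hi),
        lo=lo,
        hi=hi,
        tol=tol,
        config=cfg,
        n_classifications=n_class,
        n_undetermined=n_undet,
    )


def tin_star_surface(
    G_values: Sequence[float],
    B_E_values: Sequence[float],
    params: ModelParameters | None = None,
    cfg: SolverConfig | None = None,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Critical senescence over a (G, B_E) grid (all other rates fixed).

    Grid points in the no-resolution region (G <= B_E - 1) are emitted with
    status ``no_resolution`` and are not simulated; per-point failures are
    recorded in the table instead of aborting the sweep.
    """
    base = params or ModelParameters()
    rows = []
    for g in G_values:
        for be in B_E_values:
            row = {"G": float(g), "B_E": float(be), "tin_star": np.nan, "status": "ok"}
            if g <= be - 1:
                row["status"] = "no_resolution"
            else:
                try:
                    res = critical_senescence(
                        base.replace(G=float(g), B_E=float(be)), cfg=cfg, tol=tol
                    )
                    row["tin_star"] = res.tin_star
                except Exception as exc:  # recorded, never fatal
                    row["status"] = f"failed: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def contour_polylines(
    surface: pd.DataFrame, levels: Iterable[float]
) -> pd.DataFrame:
    """Iso-level polylines of T_in* over the (G, B_E) grid.

    Uses marching squares (contourpy) with linear interpolation; cells in
    the no-resolution region are masked out.  Returns tidy rows
    (level, line, vertex, G, B_E).
    """
    from contourpy import contour_generator

    g_vals = np.unique(surface["G"].to_numpy())
    be_vals = np.unique(surface["B_E"].to_numpy())
    z = np.full((be_vals.size, g_vals.size), np.nan)
    piv = surface.pivot(index="B_E", columns="G", values="tin_star")
    z = piv.reindex(index=be_vals, columns=g_vals).to_numpy()
    gen = contour_generator(
        x=g_vals, y=be_vals, z=np.ma.masked_invalid(z), line_type="Separate"
    )
    rows = []
    for level in levels:
        for k, line in enumerate(gen.lines(float(level))):
            for v, (x, y) in enumerate(np.asarray(line)):
                rows.append(
                    {"level": float(level), "line": k, "vertex": v, "G": x, "B_E": y}
                )
    return pd.DataFrame(rows, columns=["level", "line", "vertex", "G", "B_E"])


def clearance_sweep(
    param_name: str,
    values: Sequence[float],
    T_in_levels: Sequence[float] = DOSE_LEVELS,
    params: ModelParameters | None = None,
    cfg: SolverConfig | None = None,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Clearance time t_c versus B_2 or K_T at each dose level.

    t_c is always defined (T decays at rate >= D regardless of outcome), so
    supercritical (value, T_in) combinations are computed but flagged.
    """
    if param_name not in ("B_2", "K_T"):
        raise ValueError("param_name must be 'B_2' or 'K_T'")
    base = params or ModelParameters()
    cfg = cfg or SolverConfig()
    rows = []
    for v in values:
        if v <= 0:
            raise ValueError("swept values must be > 0")
        p = base.replace(**{param_name: float(v)})
        for tin in T_in_levels:
            row = {
                "param": param_name,
                "value": float(v),
                "T_in": float(tin),
                "t_c": np.nan,
                "outcome": "",
                "status": "ok",
            }
            try:
                traj = simulate(p, InitialCondition(T_in=float(tin)), cfg)
                row["outcome"] = traj.outcome
                if traj.outcome != RESOLVED:
                    row["status"] = "supercritical"
                row["t_c"] = clearance_time(traj, fraction)
            except HorizonTooShortError as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def dose_response(
    T_in_values: Sequence[float],
    params: ModelParameters | None = None,
    cfg: SolverConfig | None = None,
) -> pd.DataFrame:
    """Peak value/time per variable and outcome for each dose, sorted by dose."""
    base = params or ModelParameters()
    rows = []
    for tin in sorted(float(x) for x in T_in_values):
        traj = simulate(base, InitialCondition(T_in=tin), cfg)
        peaks = peak_summary(traj)
        for rec in peaks.to_dict("records"):
            rows.append({"T_in": tin, "outcome": traj.outcome, **rec})
    return pd.DataFrame(rows)
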