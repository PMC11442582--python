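"""Steady states of the injury model and their linear stability.

The model admits at most two steady states.  The trivial state (the origin,
homeostasis) always exists.  A second state with T = 0 but all other
variables strictly positive exists when G > B_E - 1; there the trivial
state is linearly stable and the non-trivial one is a saddle whose stable
manifold separates resolving from non-resolving initial conditions.  When
G < B_E - 1 only the trivial state exists and it is unstable, so no
positive dose can resolve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import STATE_VARS, ModelParameters, _jacobian, _rhs, jacobian, rhs

__all__ = [
    "SteadyState",
    "SteadyStateReport",
    "find_steady_states",
    "stability",
    "regime",
    "RESOLVING",
    "NO_RESOLUTION",
]

RESOLVING = "resolving"
NO_RESOLUTION = "no-resolution"

#: |Re(lambda)| below this counts as a zero real part ("marginal").
MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class SteadyState:
    state: tuple[float, ...]
    eigenvalues: tuple[complex, ...]
    label: str  # stable | unstable | marginal
    trivial: bool

    def as_array(self) -> np.ndarray:
        return np.asarray(self.state, dtype=float)


@dataclass
class SteadyStateReport:
    params: ModelParameters
    states: list[SteadyState]
    regime: str
    nontrivial_search_failed: bool = False

    @property
    def trivial(self) -> SteadyState:
        return next(s for s in self.states if s.trivial)

    @property
    def nontrivial(self) -> SteadyState | None:
        return next((s for s in self.states if not s.trivial), None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "regime": self.regime,
                "nontrivial_search_failed": self.nontrivial_search_failed,
                "states": [
                    {
                        "variables": dict(zip(STATE_VARS, s.state)),
                        "eigenvalues": [[ev.real, ev.imag] for ev in s.eigenvalues],
                        "label": s.label,
                        "trivial": s.trivial,
                    }
                    for s in self.states
                ],
            },
            indent=2,
        )


def stability(
    params: ModelParameters,
    state,
    resid_tol: float = 1e-8,
) -> tuple[np.ndarray, str]:
    """Eigenvalues of the Jacobian at a steady state, plus a label.

    The input must actually be a steady state (max |rhs| < ``resid_tol``);
    anything else is rejected rather than silently classified.
    """
    y = np.asarray(state, dtype=float)
    resid = np.max(np.abs(rhs(y, params)))
    if resid >= resid_tol:
        raise ValueError(f"not a steady state: max|rhs| = {resid:.3g} >= {resid_tol:g}")
    eig = np.linalg.eigvals(jacobian(y, params))
    re = eig.real
    if np.all(re < -MARGINAL_TOL):
        label = "stable"
    elif np.any(re > MARGINAL_TOL):
        label = "unstable"
    else:
        label = "marginal"
    return eig, label


def regime(params: ModelParameters) -> str:
    """Regime classification by the stated constraint G > B_E - 1.

    The boundary G = B_E - 1 is classified no-resolution (the constraint is
    strict) with a marginality warning.
    """
    if params.G > params.B_E - 1:
        return RESOLVING
    if params.G == params.B_E - 1:
        warnings.warn(
            "G == B_E - 1 exactly: marginal boundary case, classified no-resolution",
            UserWarning,
            stacklevel=2,
        )
    return NO_RESOLUTION


def _state_from_m1(m1: float, p: ModelParameters) -> np.ndarray | None:
    """Candidate T = 0 steady state parameterised by M1.

    With T = 0 and M1 > 0 the endothelial balance gives
    E = B_E*M1 / (D - B_E*M1); the M1 balance then fixes the switch level
    S = (E - D*M1)/M1, the M2 balance gives M2 = S*M1/D, and the F and C
    balances follow sequentially.  Only the self-consistency of S with
    G/((C+1)(F+1)) remains — a scalar equation in M1.
    """
    denom = p.D - p.B_E * m1
    if denom <= 0:
        return None
    E = p.B_E * m1 / denom
    S = (E - p.D * m1) / m1
    if S <= 0:
        return None
    M2 = S * m1 / p.D
    F = p.B_F * m1 / (p.K_F * M2 + p.D)
    C = p.B_C * F / (p.K_C * M2 + p.D)
    return np.array([0.0, m1, M2, E, C, F])


def _switch_mismatch(m1: float, p: ModelParameters) -> float:
    """S*(C+1)*(F+1) - G; zero exactly at the non-trivial steady state."""
    y = _state_from_m1(m1, p)
    if y is None:
        return np.nan
    _, M1, M2, E, C, F = y
    S = (E - p.D * M1) / M1
    return S * (C + 1.0) * (F + 1.0) - p.G


def _find_nontrivial(p: ModelParameters, n_scan: int = 512) -> np.ndarray | None:
    if p.B_E <= 0:
        return None  # E is forced to zero, no all-positive state exists
    hi = p.D / p.B_E
    lo = max(0.0, hi - 1.0 / p.D)
    if not lo < hi:
        return None
    # Scan the admissible open interval for a sign change, then refine.
    pad = 1e-9 * (hi - lo)
    grid = np.linspace(lo + pad, hi - pad, n_scan)
    vals = np.array([_switch_mismatch(m, p) for m in grid])
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for i in sign_change:
        try:
            m1 = brentq(_switch_mismatch, grid[i], grid[i + 1], args=(p,), xtol=1e-14)
        except ValueError:
            continue
        y = _state_from_m1(m1, p)
        if y is not None and np.all(y[1:] > 0):
            return y
    return None


def find_steady_states(
    params: ModelParameters,
    resid_tol: float = 1e-10,
) -> SteadyStateReport:
    """Locate the trivial and (if present) non-trivial steady state.

    Setting T = 0 reduces the fixed-point problem to a single scalar
    equation in M1 (see :func:`_state_from_m1`), solved by a bracketing
    scan plus Brent refinement.  A candidate is reported only if every
    non-T component is strictly positive and the full six-equation residual
    is below ``resid_tol``.
    """
    zeros = np.zeros(6)
    eig0, lab0 = stability(params, zeros)
    states = [
        SteadyState(
            state=(0.0,) * 6,
            eigenvalues=tuple(complex(v) for v in eig0),
            label=lab0,
            trivial=True,
        )
    ]

    found = _find_nontrivial(params)
    if found is not None and np.max(np.abs(_rhs(found, params))) >= resid_tol:
        found = None

    if found is not None:
        eig, lab = stability(params, found, resid_tol=1e-8)
        states.append(
            SteadyState(
                state=tuple(float(v) for v in found),
                eigenvalues=tuple(complex(v) for v in eig),
                label=lab,
                trivial=False,
            )
        )

    reg = regime(params)
    return SteadyStateReport(
        params=params,
        states=states,
        regime=reg,
        nontrivial_search_failed=found is None and reg == RESOLVING,
    )
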