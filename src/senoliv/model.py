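"""Core mass-action model of acute senescence-driven liver injury.

Six coupled ODEs describe deviations from hepatic homeostasis after a bolus
of senescent hepatocytes is introduced at time zero:

    dT/dt  = -K_T*M2*T - D*T
    dM1/dt = B_1*T + E - G/((C+1)(F+1))*M1 - D*M1
    dM2/dt = B_2*T + G/((C+1)(F+1))*M1 - D*M2
    dE/dt  = B_E*(1+E)*M1 - D*E
    dC/dt  = B_C*F - K_C*M2*C - D*C
    dF/dt  = B_F*M1 - K_F*M2*F - D*F

where T is the senescent-cell level, M1/M2 the pro-inflammatory and
pro-regenerative macrophage levels, E the activated endothelial cell level,
C the excess extracellular-matrix (collagen-I) concentration and F the
activated myofibroblast level.  All variables are dimensionless deviations
from homeostasis (homeostasis is the origin) and time is normalised on the
timescale of macrophage recruitment by activated endothelium, which is why
the E term in dM1/dt carries no rate constant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "STATE_VARS",
    "ModelParameters",
    "InitialCondition",
    "NonResolvingRegimeWarning",
    "rhs",
    "jacobian",
    "params_to_json",
    "params_from_json",
]

#: Canonical state ordering used by every array in the package.
STATE_VARS = ("T", "M1", "M2", "E", "C", "F")

#: JSON key for each parameter field (flat serialisation dialect).
_JSON_KEYS = {
    "K_T": "K_T",
    "D": "D",
    "B_1": "B1",
    "B_2": "B2",
    "G": "G",
    "B_E": "B_E",
    "B_C": "B_C",
    "K_C": "K_C",
    "B_F": "B_F",
    "K_F": "K_F",
}


class NonResolvingRegimeWarning(UserWarning):
    """Parameter set violates G > B_E - 1, so homeostasis is unstable."""


@dataclass(frozen=True)
class ModelParameters:
    """The ten nonnegative rate constants of the injury model.

    All rates default to 1, the value used for every simulation figure in
    the source study.  The initial senescent load T_in is a separate
    :class:`InitialCondition`, not a rate.

    Attributes
    ----------
    K_T : senescent-cell removal rate per pro-regenerative macrophage.
    D : death/deactivation rate shared by all species (must be > 0).
    B_1 : M1 recruitment rate per senescent cell.
    B_2 : M2 recruitment rate per senescent cell.
    G : M1 -> M2 phenotype-switch rate.
    B_E : endothelial activation rate per M1 cell.
    B_C : ECM deposition rate per myofibroblast.
    K_C : ECM breakdown rate per M2 cell.
    B_F : myofibroblast activation rate per M1 cell.
    K_F : myofibroblast deactivation rate per M2 cell.
    """

    K_T: float = 1.0
    D: float = 1.0
    B_1: float = 1.0
    B_2: float = 1.0
    G: float = 1.0
    B_E: float = 1.0
    B_C: float = 1.0
    K_C: float = 1.0
    B_F: float = 1.0
    K_F: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if self.D <= 0:
            raise ValueError(f"death/deactivation rate D must be > 0, got {self.D!r}")
        if not self.resolving_regime:
            warnings.warn(
                f"G={self.G} <= B_E-1={self.B_E - 1}: homeostasis is linearly "
                "unstable, resolution is impossible for any positive dose",
                NonResolvingRegimeWarning,
                stacklevel=3,
            )

    @property
    def resolving_regime(self) -> bool:
        """True iff G > B_E - 1 (trivial steady state stable, for D = 1)."""
        return self.G > self.B_E - 1

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class InitialCondition:
    """Initial state: a senescent bolus T_in with all else at homeostasis.

    ``state`` overrides the default (T_in, 0, 0, 0, 0, 0) vector; it exists
    for testing and for restarting integrations and must be nonnegative.
    """

    T_in: float = 0.0
    state: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.T_in) or self.T_in < 0:
            raise ValueError(f"T_in must be finite and >= 0, got {self.T_in!r}")
        if self.state is not None:
            arr = np.asarray(self.state, dtype=float)
            if arr.shape != (6,):
                raise ValueError("state override must have six components")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("state override must be finite and nonnegative")
            object.__setattr__(self, "state", tuple(float(x) for x in arr))

    def as_array(self) -> np.ndarray:
        if self.state is not None:
            return np.asarray(self.state, dtype=float)
        return np.array([self.T_in, 0.0, 0.0, 0.0, 0.0, 0.0])


def _validate_state(state: np.ndarray) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError(f"state must have six components {STATE_VARS}, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = [STATE_VARS[i] for i in np.nonzero(~np.isfinite(y))[0]]
        raise ValueError(f"non-finite state component(s): {', '.join(bad)}")
    # The phenotype-switch divisor (C+1)(F+1) only stays positive on the
    # physical domain; states behind the singularity are rejected outright.
    if y[4] < -1 or y[5] < -1:
        raise ValueError("state components C and F must be > -1 (physical domain)")
    return y


def _rhs(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Unchecked right-hand side, shared by the public API and the solver."""
    T, M1, M2, E, C, F = y
    switch = p.G / ((C + 1.0) * (F + 1.0))
    return np.array(
        [
            -p.K_T * M2 * T - p.D * T,
            p.B_1 * T + E - switch * M1 - p.D * M1,
            p.B_2 * T + switch * M1 - p.D * M2,
            p.B_E * (1.0 + E) * M1 - p.D * E,
            p.B_C * F - p.K_C * M2 * C - p.D * C,
            p.B_F * M1 - p.K_F * M2 * F - p.D * F,
        ]
    )


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivative of the state, ordered as :data:`STATE_VARS`."""
    return _rhs(_validate_state(state), params)


def _jacobian(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    T, M1, M2, E, C, F = y
    cf = (C + 1.0) * (F + 1.0)
    switch = p.G / cf
    # d(switch)/dC = -G/((C+1)^2 (F+1)); the M1 switch term is -switch*M1.
    dsw_dC = -p.G / ((C + 1.0) * cf)
    dsw_dF = -p.G / ((F + 1.0) * cf)
    J = np.zeros((6, 6))
    # T row
    J[0, 0] = -p.K_T * M2 - p.D
    J[0, 2] = -p.K_T * T
    # M1 row
    J[1, 0] = p.B_1
    J[1, 1] = -switch - p.D
    J[1, 3] = 1.0
    J[1, 4] = -dsw_dC * M1
    J[1, 5] = -dsw_dF * M1
    # M2 row
    J[2, 0] = p.B_2
    J[2, 1] = switch
    J[2, 2] = -p.D
    J[2, 4] = dsw_dC * M1
    J[2, 5] = dsw_dF * M1
    # E row
    J[3, 1] = p.B_E * (1.0 + E)
    J[3, 3] = p.B_E * M1 - p.D
    # C row
    J[4, 2] = -p.K_C * C
    J[4, 4] = -p.K_C * M2 - p.D
    J[4, 5] = p.B_C
    # F row
    J[5, 1] = p.B_F
    J[5, 2] = -p.K_F * F
    J[5, 5] = -p.K_F * M2 - p.D
    return J


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic 6x6 Jacobian d(rhs_i)/d(state_j)."""
    return _jacobian(_validate_state(state), params)


def params_to_json(params: ModelParameters, init: InitialCondition | None = None) -> str:
    """Serialise a parameter set (plus optional T_in) to a flat JSON object."""
    obj = {_JSON_KEYS[f.name]: getattr(params, f.name) for f in fields(params)}
    if init is not None:
        obj["T_in"] = init.T_in
    return json.dumps(obj, indent=2)


def params_from_json(text: str) -> tuple[ModelParameters, InitialCondition]:
    """Parse the flat JSON dialect; unknown keys are rejected.

    T_in is optional and defaults to 0 (pure homeostasis).
    """
    obj = json.loads(text)
    if not isinstance(obj, dict):
        raise ValueError("parameter JSON must be a flat object")
    known = {v: k for k, v in _JSON_KEYS.items()}
    kwargs: dict[str, float] = {}
    t_in = 0.0
    for key, value in obj.items():
        if key == "T_in":
            t_in = float(value)
        elif key in known:
            kwargs[known[key]] = float(value)
        else:
            raise ValueError(f"unknown parameter key {key!r}")
    return ModelParameters(**kwargs), InitialCondition(T_in=t_in)
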