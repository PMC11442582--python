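"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from senoliv import (
    InitialCondition,
    ModelParameters,
    SolverConfig,
    critical_senescence,
    simulate,
)


@pytest.fixture(scope="session")
def params_ones() -> ModelParameters:
    """The all-ones rate set used for every simulation figure."""
    return ModelParameters()


@pytest.fixture(scope="session")
def medium_traj(params_ones):
    """Medium-dose trajectory (T_in = 1.4, default solver)."""
    return simulate(params_ones, InitialCondition(T_in=1.4))


@pytest.fixture(scope="session")
def threshold_ones(params_ones):
    """Bisection threshold for the all-ones rate set (shared: it is slow-ish)."""
    return critical_senescence(params_ones)


def rk4_fixed_step(fun, y0: np.ndarray, t_end: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 integrator, independent of scipy.

    Oracle for cross-checking the adaptive solver: same ODE, a different
    discretisation.
    """
    n = int(round(t_end / h))
    t = np.linspace(0.0, n * h, n + 1)
    y = np.empty((n + 1, y0.size))
    y[0] = y0
    for i in range(n):
        ti, yi = t[i], y[i]
        k1 = fun(ti, yi)
        k2 = fun(ti + h / 2, yi + h / 2 * k1)
        k3 = fun(ti + h / 2, yi + h / 2 * k2)
        k4 = fun(ti + h, yi + h * k3)
        y[i + 1] = yi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return t, y


def finite_difference_jacobian(fun, y: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a vector field, column by column."""
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (fun(y + e) - fun(y - e)) / (2 * h)
    return J
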