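"""Fixed-point solution of the steady-state IOP equation.

Three routes to the same root of ``x = T_m(x)``:

* the Picard iteration with a relative stopping rule (the reference method),
* an exact closed form when the pressure-dependent route is linear
  (``kappa_hyd = 0`` makes T_m constant in x),
* a bracketed root finder on ``x - T_m(x)`` used as an independent oracle.

A numerical contraction diagnostic estimates sup |T_m'| over the physical
bracket, standing in for analytic convergence conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import Scenario, SolutionState, iteration_map, recover_state

__all__ = [
    "SolverConfig",
    "NonConvergenceError",
    "ContractionDiagnostic",
    "solve",
    "solve_fixed_point",
    "solve_root_oracle",
    "contraction_check",
]

BRACKET_UPPER_MMHG = 60.0


@dataclass(frozen=True)
class SolverConfig:
    """Stopping rule and bracket for the scalar steady-state solve."""

    rel_tol: float = 1e-11
    max_iter: int = 100
    x0: float | None = None                     # default: baseline IOP
    bracket: tuple[float, float] | None = None  # default: (p_S_b, 60)

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.bracket is not None and not self.bracket[0] < self.bracket[1]:
            raise ValueError("bracket lower bound must be below upper bound")

    def resolved(self, scenario: Scenario) -> tuple[float, tuple[float, float]]:
        bracket = self.bracket or (scenario.model.p_S_b, BRACKET_UPPER_MMHG)
        x0 = self.x0 if self.x0 is not None else scenario.model.x_b
        if not bracket[0] <= x0 <= bracket[1]:
            raise ValueError(f"x0 = {x0} outside bracket {bracket}")
        return x0, bracket


@dataclass(frozen=True)
class ContractionDiagnostic:
    """Numerical estimate of sup |dT_m/dx| over a bracket."""

    sup_abs_derivative: float
    is_contraction: bool


class NonConvergenceError(RuntimeError):
    """Picard iteration failed to meet tolerance within max_iter."""

    def __init__(self, message: str, last_iterate: float, diagnostic: ContractionDiagnostic):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostic = diagnostic


def _is_linear(scenario: Scenario) -> bool:
    # with a zero Hill asymptote the unconventional conductance is constant,
    # so T_m does not depend on x at all
    return scenario.model.hill_hyd.beta == 0.0


def _closed_form_linear(scenario: Scenario) -> float:
    m = scenario.model
    c = scenario.map_constants()
    phi = c.R_conv * m.L_unc_b
    return (c.P_tilde - c.phi_tilde + m.P_b * phi) / (1.0 + phi)


def solve_fixed_point(
    scenario: Scenario, config: SolverConfig | None = None
) -> SolutionState:
    """Solve ``x = T_m(x)`` by Picard iteration and recover the full state.

    Iterates until ``|x_{k+1} - x_k| / x_{k+1} <= rel_tol``.  In the linear
    regime the map is constant, so the fixed point is evaluated in closed
    form (method ``closed_form_linear``, one map evaluation).

    Raises
    ------
    NonConvergenceError
        If the tolerance is not met within ``max_iter`` iterations; carries
        the last iterate and the contraction diagnostic.
    """
    if config is None:
        config = SolverConfig()
    if _is_linear(scenario):
        x = _closed_form_linear(scenario)
        return recover_state(x, scenario, iterations=1, method="closed_form_linear")

    x, _ = config.resolved(scenario)
    for k in range(1, config.max_iter + 1):
        x_new = iteration_map(x, scenario)
        if abs(x_new - x) <= config.rel_tol * abs(x_new):
            return recover_state(x_new, scenario, iterations=k, method="fixed_point")
        x = x_new
    raise NonConvergenceError(
        f"fixed-point iteration did not converge in {config.max_iter} iterations "
        f"(last iterate {x:.6f} mmHg)",
        last_iterate=x,
        diagnostic=contraction_check(scenario),
    )


def solve_root_oracle(scenario: Scenario, config: SolverConfig | None = None) -> float:
    """Independent solve: bracketed root of f(x) = x - T_m(x).

    Uses Brent's method; the returned root satisfies |f| <= 1e-12 mmHg.

    Raises
    ------
    ValueError
        If f does not change sign on the bracket (out-of-range scenario).
    """
    if config is None:
        config = SolverConfig()
    _, (lo, hi) = config.resolved(scenario)

    def f(x: float) -> float:
        return x - iteration_map(x, scenario)

    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"residual does not change sign on bracket [{lo}, {hi}] mmHg"
        )
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    # polish: T_m is a contraction near the root in all supported regimes
    for _ in range(5):
        if abs(f(root)) <= 1e-12:
            break
        root = iteration_map(root, scenario)
    return root


def solve(
    scenario: Scenario,
    config: SolverConfig | None = None,
    method: str = "fixed_point",
) -> SolutionState:
    """Solve a scenario by the requested method and recover the full state.

    ``fixed_point`` is the reference Picard iteration (closed form in the
    linear regime); ``bracketed_root`` uses the independent root finder,
    which also handles non-contractive regimes where Picard diverges.
    """
    if method == "fixed_point":
        return solve_fixed_point(scenario, config)
    if method == "bracketed_root":
        x = solve_root_oracle(scenario, config)
        return recover_state(x, scenario, iterations=0, method="bracketed_root")
    raise ValueError(f"unknown method {method!r}")


def contraction_check(
    scenario: Scenario,
    bracket: tuple[float, float] | None = None,
    n_points: int = 2001,
) -> ContractionDiagnostic:
    """Estimate sup |T_m'| on the bracket by dense central differences."""
    if bracket is None:
        bracket = (scenario.model.p_S_b, BRACKET_UPPER_MMHG)
    lo, hi = bracket
    xs = np.linspace(lo, hi, n_points)
    ts = np.array([iteration_map(float(x), scenario) for x in xs])
    # central differences on the interior nodes
    deriv = (ts[2:] - ts[:-2]) / (xs[2:] - xs[:-2])
    sup = float(np.max(np.abs(deriv))) if deriv.size else 0.0
    return ContractionDiagnostic(sup_abs_derivative=sup, is_contraction=sup < 1.0)
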