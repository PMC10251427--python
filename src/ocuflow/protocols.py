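"""Simulation protocols: resistance sweep, drug-therapy sweep, sensitivity.

Phase 1 raises the trabecular-meshwork resistance from baseline to a
pathological multiple with no drug.  Phase 2 holds the resistance at its
pathological value and steps the cumulative absorbed drug mass day by day.
Results are emitted as tidy tables in reporting units (mmHg, uL/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .model_core import Scenario, SolutionState, absorbed_mass
from .solver import SolverConfig, solve
from .units_and_params import CalibratedModel, DrugRegimen, convert_flow

__all__ = [
    "SWEEP_COLUMNS",
    "SweepResult",
    "run_phase1",
    "run_phase2",
    "sensitivity_eta",
    "mass_audit",
]

SWEEP_COLUMNS = [
    "axis_value",
    "iop_mmHg",
    "p_pc_mmHg",
    "p_ac_mmHg",
    "q_conv_ul_min",
    "q_unc_ul_min",
    "q_unc_hyd_ul_min",
    "q_unc_drug_ul_min",
    "residual_mmHg",
    "iterations",
    "method",
]


def _row(axis_value: float, state: SolutionState) -> dict[str, Any]:
    return {
        "axis_value": axis_value,
        "iop_mmHg": state.x,
        "p_pc_mmHg": state.z,
        "p_ac_mmHg": state.y,
        "q_conv_ul_min": convert_flow(state.Q_conv, "m3/s", "uL/min"),
        "q_unc_ul_min": convert_flow(state.Q_unc, "m3/s", "uL/min"),
        "q_unc_hyd_ul_min": convert_flow(state.Q_unc_hyd, "m3/s", "uL/min"),
        "q_unc_drug_ul_min": convert_flow(state.Q_unc_drug, "m3/s", "uL/min"),
        "residual_mmHg": state.residual,
        "iterations": state.iterations,
        "method": state.method,
    }


@dataclass
class SweepResult:
    """Ordered table of solved steady states along one axis (eta or day)."""

    axis: str                       # "eta" | "day"
    rows: list[dict[str, Any]]
    states: list[SolutionState]
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=SWEEP_COLUMNS)

    @property
    def max_iterations(self) -> int:
        return max(s.iterations for s in self.states)


def run_phase1(
    model: CalibratedModel,
    eta_max: float = 3.0,
    n_steps: int = 201,
    kappa_hyd: float | None = None,
    config: SolverConfig | None = None,
    method: str = "fixed_point",
) -> SweepResult:
    """Sweep the resistance multiplier eta over a uniform grid [1, eta_max].

    No drug throughout.  `kappa_hyd`, if given, overrides the model's gain
    for the pressure-dependent route.
    """
    if eta_max < 1.0:
        raise ValueError("eta_max must be >= 1")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if kappa_hyd is not None:
        model = model.with_kappa(kappa_hyd=kappa_hyd)

    etas = np.linspace(1.0, eta_max, n_steps)
    rows, states = [], []
    for eta in etas:
        try:
            state = solve(Scenario(model=model, eta=float(eta)), config, method)
        except Exception as exc:  # annotate with grid position
            raise RuntimeError(f"phase-1 solve failed at eta = {eta:g}") from exc
        rows.append(_row(float(eta), state))
        states.append(state)
    meta = {
        "protocol": "phase1",
        "eta_max": eta_max,
        "n_steps": n_steps,
        "kappa_hyd": model.kappa_hyd,
        "kappa_drug": model.kappa_drug,
    }
    return SweepResult(axis="eta", rows=rows, states=states, metadata=meta)


def run_phase2(
    model: CalibratedModel,
    regimen: DrugRegimen | None = None,
    eta_path: float = 3.0,
    kappa_hyd: float | None = None,
    config: SolverConfig | None = None,
    method: str = "fixed_point",
) -> SweepResult:
    """Hold eta at its pathological value and step the drug day 0..N_days.

    The cumulative absorbed mass after `day` drops drives the drug source.
    Each row also reports the percent IOP reduction relative to day 0.
    Strongly non-contractive regimes (large kappa_hyd) need
    ``method="bracketed_root"``: Picard diverges where sup |T_m'| > 1.
    """
    if regimen is None:
        regimen = model.regimen
    if kappa_hyd is not None:
        model = model.with_kappa(kappa_hyd=kappa_hyd)

    rows, states = [], []
    iop0 = None
    for day in range(regimen.N_days + 1):
        m_abs = absorbed_mass(day, regimen)
        try:
            state = solve(
                Scenario(model=model, eta=eta_path, m_abs_ug=m_abs), config, method
            )
        except Exception as exc:
            raise RuntimeError(f"phase-2 solve failed at day = {day}") from exc
        if iop0 is None:
            iop0 = state.x
        row = _row(float(day), state)
        row["m_abs_ug"] = m_abs
        row["iop_reduction_mmHg"] = iop0 - state.x
        row["iop_reduction_pct"] = 100.0 * (iop0 - state.x) / iop0
        rows.append(row)
        states.append(state)
    meta = {
        "protocol": "phase2",
        "eta_path": eta_path,
        "kappa_hyd": model.kappa_hyd,
        "kappa_drug": model.kappa_drug,
        "regimen": {
            "F": regimen.F,
            "m_onedrop_ug": regimen.m_onedrop_ug,
            "N_days": regimen.N_days,
        },
    }
    return SweepResult(axis="day", rows=rows, states=states, metadata=meta)


def sensitivity_eta(model: CalibratedModel, eta: float) -> float:
    """d(IOP)/d(eta) of the linear-regime closed-form solution, mmHg.

    Valid for the linear pressure route (kappa_hyd = 0), where the steady
    state has a closed form; phi and the source pressure are evaluated at
    the current eta, making this the exact derivative.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    R_cb = model.R_conv_b
    phi = eta * R_cb * model.L_unc_b
    P_tilde = model.p_ev_b + (eta * R_cb + model.R_AC_b) * model.Q_total_b
    return R_cb * (
        model.Q_total_b / (1.0 + phi)
        + model.L_unc_b * (model.P_b - P_tilde) / (1.0 + phi) ** 2
    )


def mass_audit(sweep: SweepResult) -> float:
    """Max |Q_conv + Q_unc - Q_total_b| over the sweep, in uL/min.

    The steady state conserves fluid mass exactly; the residual measures
    solver accuracy.
    """
    q_bar = convert_flow(sweep.states[0].Q12, "m3/s", "uL/min")
    worst = 0.0
    for row in sweep.rows:
        dev = abs(row["q_conv_ul_min"] + row["q_unc_ul_min"] - q_bar)
        worst = max(worst, dev)
    return worst
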