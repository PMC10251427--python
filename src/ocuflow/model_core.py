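"""Constitutive laws and the steady-state circuit equations.

The nonlinear steady state is reduced to a single scalar equation
``x = T_m(x)`` for the intraocular pressure x.  Everything else — chamber
pressures, flow decomposition — is recovered algebraically from a solved x.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units_and_params import CalibratedModel, DrugRegimen, HillParams

__all__ = [
    "hill",
    "z_of_x",
    "l_unc_hyd",
    "q_unc_drug",
    "absorbed_mass",
    "Scenario",
    "MapConstants",
    "SolutionState",
    "iteration_map",
    "recover_state",
]


def hill(xi: float, params: HillParams) -> float:
    """Hill saturation law beta * xi^p / (xi^p + K_act^p).

    Vanishes at xi = 0, reaches beta/2 at xi = K_act, saturates at beta.
    """
    if xi < 0:
        raise ValueError(f"Hill argument must be >= 0, got {xi}")
    if xi == 0.0:
        return 0.0
    # branch on the ratio so neither power can overflow
    ratio = xi / params.K_act
    if ratio >= 1.0:
        r = ratio ** (-params.p)  # in (0, 1]
        return params.beta / (1.0 + r)
    t = ratio ** params.p  # in [0, 1); harmless underflow to 0
    return params.beta * t / (1.0 + t)


def z_of_x(x: float, model: CalibratedModel) -> float:
    """Normalized positive deviation of IOP above baseline.

    ``Z = max((x - x_b) / (x_b - P_b), 0)`` — zero whenever x <= x_b, so the
    pressure-dependent route only activates above the baseline IOP.  The
    kink at x = x_b is intentional (hard clamp, no smoothing).
    """
    return max((x - model.x_b) / model.denom_Z, 0.0)


def l_unc_hyd(Z: float, model: CalibratedModel) -> float:
    """Pressure-dependent unconventional conductance L_unc_b * (1 + f_H(Z))."""
    if Z < 0:
        raise ValueError(f"Z must be >= 0, got {Z}")
    return model.L_unc_b * (1.0 + hill(Z, model.hill_hyd))


def q_unc_drug(m_abs: float, model: CalibratedModel) -> float:
    """Drug-driven unconventional flow source f_H(m), m^3/s.

    Independent of the pressure state; saturates at the route's beta.
    """
    if m_abs < 0:
        raise ValueError(f"absorbed mass must be >= 0, got {m_abs}")
    return hill(m_abs, model.hill_drug)


def absorbed_mass(day: int, regimen: DrugRegimen) -> float:
    """Cumulative absorbed drug mass (ug) after `day` daily drops."""
    if day < 0:
        raise ValueError(f"day must be >= 0, got {day}")
    return regimen.F * regimen.m_onedrop_ug * day


@dataclass(frozen=True)
class Scenario:
    """One steady-state problem: resistance multiplier, drug mass, model."""

    model: CalibratedModel
    eta: float = 1.0
    m_abs_ug: float = 0.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.m_abs_ug < 0:
            raise ValueError(f"m_abs_ug must be >= 0, got {self.m_abs_ug}")

    @property
    def R_conv(self) -> float:
        """Trabecular resistance eta * R_conv_b, mmHg s m^-3."""
        return self.eta * self.model.R_conv_b

    @property
    def R_tot(self) -> float:
        return self.R_conv + self.model.R_AC_b

    def map_constants(self) -> "MapConstants":
        m = self.model
        return MapConstants(
            P_tilde=m.p_ev_b + self.R_tot * m.Q_total_b,
            phi_tilde=self.R_conv * q_unc_drug(self.m_abs_ug, m),
            R_conv=self.R_conv,
            R_tot=self.R_tot,
        )


@dataclass(frozen=True)
class MapConstants:
    """x-independent pieces of the iteration map for one scenario."""

    P_tilde: float      # mmHg
    phi_tilde: float    # mmHg
    R_conv: float       # mmHg s m^-3
    R_tot: float        # mmHg s m^-3


def iteration_map(x: float, scenario: Scenario) -> float:
    """The fixed-point map T_m whose fixed point is the steady-state IOP.

    ``T_m(x) = (P_tilde - phi_tilde + P_b * phi(x)) / (1 + phi(x))`` with
    ``phi(x) = R_conv * L_unc_hyd(Z(x))``.  The drug term enters with a
    negative sign, so increasing drug mass lowers the map pointwise.
    """
    m = scenario.model
    c = scenario.map_constants()
    phi = c.R_conv * l_unc_hyd(z_of_x(x, m), m)
    return (c.P_tilde - c.phi_tilde + m.P_b * phi) / (1.0 + phi)


@dataclass(frozen=True)
class SolutionState:
    """Converged steady state: pressures (mmHg), flows (m^3/s), diagnostics."""

    x: float            # IOP
    z: float            # posterior chamber pressure
    y: float            # anterior chamber pressure
    w: float            # y - p_S_b
    Z_val: float        # activation variable
    Q12: float
    Q23: float
    Q_conv: float
    Q_unc: float
    Q_unc_hyd: float
    Q_unc_drug: float
    residual: float     # x - T_m(x), mmHg
    iterations: int
    method: str         # fixed_point | closed_form_linear | bracketed_root

    @property
    def Q_out(self) -> float:
        """Total drainage Q_conv + Q_unc, m^3/s."""
        return self.Q_conv + self.Q_unc


def recover_state(
    x: float,
    scenario: Scenario,
    iterations: int = 0,
    method: str = "fixed_point",
) -> SolutionState:
    """Recover the full circuit state from a solved IOP.

    Chamber pressures follow from Ohm's law along the secretion path at the
    fixed total flow; branch flows from the constitutive laws at x.
    """
    m = scenario.model
    z = x + m.Q_total_b / m.L_PC
    y = x - m.Q_total_b / m.L_AC
    w = y - m.p_S_b
    Z = z_of_x(x, m)
    L_conv = m.L_conv_b / scenario.eta
    Q_unc_hyd = l_unc_hyd(Z, m) * w
    Q_unc_drug = q_unc_drug(scenario.m_abs_ug, m)
    return SolutionState(
        x=x,
        z=z,
        y=y,
        w=w,
        Z_val=Z,
        Q12=m.L_PC * (z - x),
        Q23=m.L_AC * (x - y),
        Q_conv=L_conv * (y - m.p_ev_b),
        Q_unc=Q_unc_hyd + Q_unc_drug,
        Q_unc_hyd=Q_unc_hyd,
        Q_unc_drug=Q_unc_drug,
        residual=x - iteration_map(x, scenario),
        iterations=iterations,
        method=method,
    )
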