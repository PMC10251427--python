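"""Unit conversions and calibration of the hydraulic circuit constants.

The model works internally in a fixed unit convention:

* pressures in mmHg,
* volumetric flow rates in m^3/s,
* hydraulic conductances in m^3 s^-1 mmHg^-1.

Microliters per minute and pascals appear only at I/O boundaries.  All
conductances are calibrated from a baseline physiology record via the
discrete Ohm/Darcy law ``L = Q / (pressure drop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MMHG_PER_PA",
    "PA_PER_MMHG",
    "M3S_PER_ULMIN",
    "IOP_PATH_MMHG",
    "BETA_MAX_HYD_DEFAULT",
    "BETA_MAX_DRUG_DEFAULT",
    "KAPPA_DRUG_DEFAULT",
    "convert_pressure",
    "convert_flow",
    "poiseuille_specific_conductance",
    "HillParams",
    "DrugRegimen",
    "BaselinePhysiology",
    "CalibratedModel",
    "CalibrationError",
    "calibrate",
]

PA_PER_MMHG = 133.322
MMHG_PER_PA = 1.0 / PA_PER_MMHG
#: 1 uL/min in m^3/s
M3S_PER_ULMIN = 1e-9 / 60.0

#: conventional clinical threshold for pathological IOP
IOP_PATH_MMHG = 21.0

#: asymptotic gain of the pressure-dependent unconventional-route conductance
BETA_MAX_HYD_DEFAULT = 0.1493
#: asymptotic drug-driven unconventional flow source, m^3/s
BETA_MAX_DRUG_DEFAULT = 7.87e-11
#: default fraction of the maximal drug gain used in the therapy protocol
KAPPA_DRUG_DEFAULT = 0.33

_PRESSURE_UNITS = {"Pa", "mmHg"}
_FLOW_UNITS = {"uL/min", "m3/s"}
_FLOW_ALIASES = {
    "uL/min": "uL/min",
    "ul/min": "uL/min",
    "μL/min": "uL/min",
    "µL/min": "uL/min",
    "m3/s": "m3/s",
    "m^3/s": "m3/s",
}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between Pa and mmHg (1 mmHg = 133.322 Pa)."""
    for unit in (from_unit, to_unit):
        if unit not in _PRESSURE_UNITS:
            raise ValueError(
                f"unknown pressure unit {unit!r}; expected one of {sorted(_PRESSURE_UNITS)}"
            )
    if from_unit == to_unit:
        return value
    if from_unit == "Pa":
        return value * MMHG_PER_PA
    return value * PA_PER_MMHG


def convert_flow(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a volumetric flow rate between uL/min and m^3/s."""
    try:
        from_unit = _FLOW_ALIASES[from_unit]
        to_unit = _FLOW_ALIASES[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown flow unit {exc.args[0]!r}; expected one of {sorted(_FLOW_UNITS)}"
        ) from None
    if from_unit == to_unit:
        return value
    if from_unit == "uL/min":
        return value * M3S_PER_ULMIN
    return value / M3S_PER_ULMIN


def poiseuille_specific_conductance(a: float, b: float, mu: float) -> float:
    """Specific hydraulic conductance 2 a^2 / (3 mu b) of a plane channel.

    Parameters
    ----------
    a : half-height of the channel (m)
    b : length of the channel (m)
    mu : dynamic viscosity (Pa s)

    Returns
    -------
    float
        Specific conductance in m s^-1 Pa^-1 relating the mean velocity to
        the pressure drop along the channel.
    """
    if a <= 0 or b <= 0 or mu <= 0:
        raise ValueError("a, b, and mu must all be strictly positive")
    return 2.0 * a * a / (3.0 * mu * b)


@dataclass(frozen=True)
class HillParams:
    """Parameters of a Hill saturation law beta * xi^p / (xi^p + K_act^p)."""

    beta: float
    K_act: float
    p: int = 4

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"Hill asymptote beta must be >= 0, got {self.beta}")
        if self.K_act <= 0:
            raise ValueError(f"Hill activation constant must be > 0, got {self.K_act}")
        if self.p < 1:
            raise ValueError(f"Hill exponent must be >= 1, got {self.p}")


@dataclass(frozen=True)
class DrugRegimen:
    """Topical drug therapy: daily drops with fractional bioavailability.

    ``M_tot_abs = F * m_onedrop * N_days`` is the total mass (ug) actually
    absorbed by the anterior segment over the full course.
    """

    F: float = 0.05
    m_onedrop_ug: float = 1.5625
    N_days: int = 14

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"bioavailability F must be in [0, 1], got {self.F}")
        if self.m_onedrop_ug <= 0:
            raise ValueError(f"drop mass must be > 0, got {self.m_onedrop_ug}")
        if self.N_days < 0:
            raise ValueError(f"N_days must be >= 0, got {self.N_days}")

    @property
    def M_tot_abs_ug(self) -> float:
        return self.F * self.m_onedrop_ug * self.N_days


@dataclass(frozen=True)
class BaselinePhysiology:
    """Baseline (healthy) pressures and flow rates of the anterior segment.

    Pressures are mmHg; flows are uL/min at this boundary.  The total
    secretion rate defaults to the sum of the two drainage components so
    that the baseline is exactly mass balanced.
    """

    x_b: float = 15.0                                   # baseline IOP
    p_PC_b: float = 15.5                                # posterior chamber
    p_AC_b: float = 1950.0 * MMHG_PER_PA                # anterior chamber (~14.63)
    p_ev_b: float = 8.0                                 # episcleral veins
    p_S_b: float = 11.0                                 # suprachoroidal space
    Q_conv_b_ulmin: float = 2.45                        # conventional route
    Q_unc_hyd_b_ulmin: float = 0.3                      # unconventional route
    Q_total_b_ulmin: float | None = None                # secretion; default = sum

    def __post_init__(self) -> None:
        for name in ("x_b", "p_PC_b", "p_AC_b", "p_ev_b", "p_S_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"baseline pressure {name} must be > 0")
        if not self.p_PC_b > self.x_b > self.p_AC_b > self.p_ev_b:
            raise ValueError(
                "baseline pressure cascade violated: need p_PC_b > x_b > p_AC_b > p_ev_b"
            )
        if not self.p_AC_b > self.p_S_b:
            raise ValueError("baseline requires p_AC_b > p_S_b")
        if self.Q_conv_b_ulmin <= 0 or self.Q_unc_hyd_b_ulmin <= 0:
            raise ValueError("baseline flow rates must be > 0")
        if self.Q_total_b_ulmin is None:
            object.__setattr__(
                self,
                "Q_total_b_ulmin",
                self.Q_conv_b_ulmin + self.Q_unc_hyd_b_ulmin,
            )

    # internal-unit views
    @property
    def Q_conv_b(self) -> float:
        """Conventional baseline flow, m^3/s."""
        return convert_flow(self.Q_conv_b_ulmin, "uL/min", "m3/s")

    @property
    def Q_unc_hyd_b(self) -> float:
        """Unconventional (hydraulic) baseline flow, m^3/s."""
        return convert_flow(self.Q_unc_hyd_b_ulmin, "uL/min", "m3/s")

    @property
    def Q_total_b(self) -> float:
        """Total secretion rate, m^3/s."""
        return convert_flow(self.Q_total_b_ulmin, "uL/min", "m3/s")


class CalibrationError(ValueError):
    """Raised when the baseline record yields a non-physical calibration."""


@dataclass(frozen=True)
class CalibratedModel:
    """All constants of the steady-state circuit, in internal units.

    Conductances are m^3 s^-1 mmHg^-1.  ``P_b`` is the reference pressure
    of the relief-valve activation variable and ``denom_Z = x_b - P_b`` its
    (positive) normalization.
    """

    baseline: BaselinePhysiology
    L_PC: float
    L_AC: float
    L_conv_b: float
    L_unc_b: float
    P_b: float
    denom_Z: float
    hill_hyd: HillParams
    hill_drug: HillParams
    kappa_hyd: float
    kappa_drug: float
    beta_max_hyd: float
    beta_max_drug: float
    regimen: DrugRegimen = field(default_factory=DrugRegimen)

    @property
    def x_b(self) -> float:
        return self.baseline.x_b

    @property
    def p_ev_b(self) -> float:
        return self.baseline.p_ev_b

    @property
    def p_S_b(self) -> float:
        return self.baseline.p_S_b

    @property
    def Q_total_b(self) -> float:
        return self.baseline.Q_total_b

    @property
    def R_conv_b(self) -> float:
        """Baseline trabecular-meshwork resistance, mmHg s m^-3."""
        return 1.0 / self.L_conv_b

    @property
    def R_AC_b(self) -> float:
        return 1.0 / self.L_AC

    def with_kappa(
        self,
        kappa_hyd: float | None = None,
        kappa_drug: float | None = None,
    ) -> "CalibratedModel":
        """Return a copy with re-scaled Hill asymptotes (same calibration)."""
        kh = self.kappa_hyd if kappa_hyd is None else kappa_hyd
        kd = self.kappa_drug if kappa_drug is None else kappa_drug
        if kh < 0 or kd < 0:
            raise ValueError("kappa gains must be >= 0")
        return replace(
            self,
            kappa_hyd=kh,
            kappa_drug=kd,
            hill_hyd=replace(self.hill_hyd, beta=kh * self.beta_max_hyd),
            hill_drug=replace(self.hill_drug, beta=kd * self.beta_max_drug),
        )


def calibrate(
    baseline: BaselinePhysiology | None = None,
    kappa_hyd: float = 0.99,
    kappa_drug: float = KAPPA_DRUG_DEFAULT,
    regimen: DrugRegimen | None = None,
    beta_max_hyd: float = BETA_MAX_HYD_DEFAULT,
    beta_max_drug: float = BETA_MAX_DRUG_DEFAULT,
    hill_exponent: int = 4,
    iop_path: float = IOP_PATH_MMHG,
) -> CalibratedModel:
    """Calibrate all circuit constants from a baseline physiology record.

    Each conductance is fixed by Ohm's law across its branch at baseline:

    * ``L_PC = Q_total_b / (p_PC_b - x_b)``
    * ``L_AC = Q_total_b / (x_b - p_AC_b)``
    * ``L_conv_b = Q_conv_b / (p_AC_b - p_ev_b)``
    * ``L_unc_b = Q_unc_hyd_b / (p_AC_b - p_S_b)``

    The activation constant of the pressure route places the Hill midpoint
    halfway between the baseline and the pathological IOP; the drug route's
    midpoint sits at half the total absorbed mass of the full regimen.

    Raises
    ------
    CalibrationError
        If any baseline pressure drop is non-positive.
    """
    if baseline is None:
        baseline = BaselinePhysiology()
    if regimen is None:
        regimen = DrugRegimen()
    if kappa_hyd < 0 or kappa_drug < 0:
        raise ValueError("kappa gains must be >= 0")
    if beta_max_hyd < 0 or beta_max_drug < 0:
        raise ValueError("beta_max gains must be >= 0")

    drops = {
        "p_PC_b - x_b": baseline.p_PC_b - baseline.x_b,
        "x_b - p_AC_b": baseline.x_b - baseline.p_AC_b,
        "p_AC_b - p_ev_b": baseline.p_AC_b - baseline.p_ev_b,
        "p_AC_b - p_S_b": baseline.p_AC_b - baseline.p_S_b,
    }
    for name, drop in drops.items():
        if drop <= 0:
            raise CalibrationError(f"non-positive baseline pressure drop {name} = {drop}")

    L_PC = baseline.Q_total_b / drops["p_PC_b - x_b"]
    L_AC = baseline.Q_total_b / drops["x_b - p_AC_b"]
    L_conv_b = baseline.Q_conv_b / drops["p_AC_b - p_ev_b"]
    L_unc_b = baseline.Q_unc_hyd_b / drops["p_AC_b - p_S_b"]

    P_b = baseline.p_S_b + baseline.Q_total_b / L_AC
    denom_Z = baseline.x_b - P_b
    if denom_Z <= 0:
        raise CalibrationError(f"x_b - P_b = {denom_Z} must be > 0")

    p05 = 0.5 * (baseline.x_b + iop_path)
    K_act_hyd = (p05 - baseline.x_b) / denom_Z
    K_act_drug = 0.5 * regimen.M_tot_abs_ug
    if K_act_drug <= 0:
        raise CalibrationError("drug regimen yields non-positive K_act_drug")

    return CalibratedModel(
        baseline=baseline,
        L_PC=L_PC,
        L_AC=L_AC,
        L_conv_b=L_conv_b,
        L_unc_b=L_unc_b,
        P_b=P_b,
        denom_Z=denom_Z,
        hill_hyd=HillParams(beta=kappa_hyd * beta_max_hyd, K_act=K_act_hyd, p=hill_exponent),
        hill_drug=HillParams(beta=kappa_drug * beta_max_drug, K_act=K_act_drug, p=hill_exponent),
        kappa_hyd=kappa_hyd,
        kappa_drug=kappa_drug,
        beta_max_hyd=beta_max_hyd,
        beta_max_drug=beta_max_drug,
        regimen=regimen,
    )
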