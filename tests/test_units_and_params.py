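import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ocuflow import (
    BaselinePhysiology,
    CalibrationError,
    DrugRegimen,
    HillParams,
    calibrate,
    convert_flow,
    convert_pressure,
    poiseuille_specific_conductance,
)


def sig3(x):
    """Round to 3 significant figures."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 2)


class TestConvertPressure:
    def test_anterior_chamber_reference_value(self):
        # 1950 Pa is the anterior-chamber baseline, quoted as 14.62 mmHg
        assert convert_pressure(1950.0, "Pa", "mmHg") == pytest.approx(14.6264, abs=5e-4)

    def test_zero(self):
        assert convert_pressure(0.0, "Pa", "mmHg") == 0.0

    def test_identity_same_unit(self):
        assert convert_pressure(12.5, "mmHg", "mmHg") == 12.5

    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_round_trip(self, value):
        back = convert_pressure(convert_pressure(value, "mmHg", "Pa"), "Pa", "mmHg")
        assert back == pytest.approx(value, rel=1e-14, abs=1e-14)

    @pytest.mark.parametrize("bad", ["kPa", "psi", "", "mmhg"])
    def test_unknown_unit(self, bad):
        with pytest.raises(ValueError, match="unknown pressure unit"):
            convert_pressure(1.0, bad, "mmHg")


class TestConvertFlow:
    def test_total_secretion_reference_value(self):
        assert convert_flow(2.75, "uL/min", "m3/s") == pytest.approx(4.5833e-11, rel=1e-4)

    def test_unconventional_reference_value(self):
        # 0.3 uL/min corresponds to 5e-12 m^3/s
        assert convert_flow(0.3, "uL/min", "m3/s") == pytest.approx(5.0e-12, rel=1e-12)

    def test_zero(self):
        assert convert_flow(0.0, "uL/min", "m3/s") == 0.0

    def test_unicode_alias(self):
        assert convert_flow(1.0, "μL/min", "m3/s") == convert_flow(1.0, "uL/min", "m3/s")

    @given(st.floats(min_value=0, max_value=1e3, allow_nan=False))
    def test_round_trip(self, value):
        back = convert_flow(convert_flow(value, "uL/min", "m3/s"), "m3/s", "uL/min")
        assert back == pytest.approx(value, rel=1e-13, abs=1e-18)

    def test_unknown_unit(self):
        with pytest.raises(ValueError, match="unknown flow unit"):
            convert_flow(1.0, "L/s", "m3/s")


class TestPoiseuille:
    def test_algebraic_identity(self):
        assert poiseuille_specific_conductance(1.0, 1.0, 2.0 / 3.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # 2 * (1e-3)^2 / (3 * 1e-3 * 1e-2) = 2/30
        got = poiseuille_specific_conductance(1e-3, 1e-2, 1e-3)
        assert got == pytest.approx(2.0 / 30.0, rel=1e-14)

    @given(
        a=st.floats(min_value=1e-6, max_value=1e3),
        b=st.floats(min_value=1e-6, max_value=1e3),
        mu=st.floats(min_value=1e-6, max_value=1e3),
    )
    def test_scaling_laws(self, a, b, mu):
        base = poiseuille_specific_conductance(a, b, mu)
        assert poiseuille_specific_conductance(2 * a, b, mu) == pytest.approx(4 * base, rel=1e-12)
        assert poiseuille_specific_conductance(a, 2 * b, mu) == pytest.approx(base / 2, rel=1e-12)
        assert poiseuille_specific_conductance(a, b, 2 * mu) == pytest.approx(base / 2, rel=1e-12)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ValueError):
            poiseuille_specific_conductance(*args)


class TestBaselinePhysiology:
    def test_default_total_is_mass_balanced(self, baseline):
        assert baseline.Q_total_b_ulmin == pytest.approx(2.75)
        assert baseline.Q_total_b == pytest.approx(
            baseline.Q_conv_b + baseline.Q_unc_hyd_b, rel=1e-15
        )

    def test_explicit_total_override(self):
        b = BaselinePhysiology(Q_total_b_ulmin=2.74)
        assert b.Q_total_b_ulmin == 2.74

    def test_pressure_cascade_enforced(self):
        with pytest.raises(ValueError, match="cascade"):
            BaselinePhysiology(p_PC_b=14.0)  # below x_b

    def test_suprachoroidal_below_anterior(self):
        with pytest.raises(ValueError):
            BaselinePhysiology(p_S_b=14.9)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            BaselinePhysiology(p_ev_b=-1.0)


class TestDrugRegimen:
    def test_total_absorbed_mass(self, regimen):
        assert regimen.M_tot_abs_ug == pytest.approx(1.09375, rel=1e-15)

    def test_invalid_bioavailability(self):
        with pytest.raises(ValueError):
            DrugRegimen(F=1.5)

    def test_invalid_drop_mass(self):
        with pytest.raises(ValueError):
            DrugRegimen(m_onedrop_ug=0.0)


class TestHillParams:
    def test_defaults_exponent_four(self):
        assert HillParams(beta=1.0, K_act=1.0).p == 4

    @pytest.mark.parametrize(
        "kwargs", [{"beta": -1.0, "K_act": 1.0}, {"beta": 1.0, "K_act": 0.0}, {"beta": 1.0, "K_act": 1.0, "p": 0}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            HillParams(**kwargs)


class TestCalibrate:
    """The four conductances and derived constants against their printed values."""

    def test_posterior_chamber_conductance(self, model):
        assert sig3(model.L_PC) == pytest.approx(9.17e-11)

    def test_anterior_chamber_conductance(self, model):
        assert sig3(model.L_AC) == pytest.approx(1.23e-10)

    def test_conventional_conductance(self, model):
        assert sig3(model.L_conv_b) == pytest.approx(6.16e-12)

    def test_unconventional_conductance(self, model):
        assert sig3(model.L_unc_b) == pytest.approx(1.38e-12)

    def test_reference_pressure_offset(self, model):
        assert model.denom_Z == pytest.approx(3.62, abs=0.01)
        assert model.denom_Z == model.x_b - model.P_b

    def test_hydraulic_activation_constant(self, model):
        # midpoint between baseline (15) and pathological (21) IOP, normalized
        assert model.hill_hyd.K_act == pytest.approx(3.0 / model.denom_Z, rel=1e-15)
        assert model.hill_hyd.K_act == pytest.approx(0.827, abs=5e-4)

    def test_drug_activation_constant(self, model):
        assert model.hill_drug.K_act == pytest.approx(0.546875, rel=1e-15)

    def test_hill_asymptotes_scaled_by_kappa(self, model):
        assert model.hill_hyd.beta == pytest.approx(0.99 * 0.1493, rel=1e-15)
        assert model.hill_drug.beta == pytest.approx(0.33 * 7.87e-11, rel=1e-15)

    def test_ohm_law_round_trip(self, model, baseline):
        """L * (baseline pressure drop) recovers each printed baseline flow."""
        b = baseline
        assert model.L_PC * (b.p_PC_b - b.x_b) == pytest.approx(b.Q_total_b, rel=1e-14)
        assert model.L_AC * (b.x_b - b.p_AC_b) == pytest.approx(b.Q_total_b, rel=1e-14)
        assert model.L_conv_b * (b.p_AC_b - b.p_ev_b) == pytest.approx(b.Q_conv_b, rel=1e-14)
        assert model.L_unc_b * (b.p_AC_b - b.p_S_b) == pytest.approx(b.Q_unc_hyd_b, rel=1e-14)

    def test_with_kappa_rescales_only_gains(self, model):
        linear = model.with_kappa(kappa_hyd=0.0)
        assert linear.hill_hyd.beta == 0.0
        assert linear.hill_hyd.K_act == model.hill_hyd.K_act
        assert linear.L_conv_b == model.L_conv_b

    def test_zero_regimen_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            calibrate(regimen=DrugRegimen(N_days=0))

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            calibrate(kappa_hyd=-0.5)
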