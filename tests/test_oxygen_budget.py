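"""Henry's-law oxygen budget, heart rate and Fick surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snailo2.constants import DEFAULT_CONSTANTS, R_GAS_L_ATM, kelvin
from snailo2.oxygen_budget import (
    BondingModel,
    HeartModel,
    ambient_saturation,
    bonded_concentrations,
    diffusive_surface_fick,
    dissolved_check,
    dissolved_concentration,
    heart_rate,
    henry_dissolved_concentration,
    molar_to_volumetric,
    omega_max,
    outlet_velocity,
)

K = DEFAULT_CONSTANTS


class TestHenryConcentrations:
    def test_venous_concentration(self):
        assert henry_dissolved_concentration(K.p_O2_vein) == pytest.approx(0.0753, rel=1e-3)

    def test_arterial_concentration(self):
        assert henry_dissolved_concentration(K.p_O2_artery) == pytest.approx(0.381, rel=2e-3)

    def test_zero_pressure_gives_zero(self):
        assert henry_dissolved_concentration(0.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(0.0, 5e4), scale=st.floats(0.1, 10.0))
    def test_linear_in_partial_pressure(self, p, scale):
        assert henry_dissolved_concentration(p * scale) == pytest.approx(
            scale * henry_dissolved_concentration(p), rel=1e-14, abs=1e-300
        )

    def test_ambient_saturation(self):
        assert ambient_saturation() == pytest.approx(0.666, rel=1e-3)

    def test_ambient_agrees_with_literature_solubility(self):
        assert ambient_saturation() == pytest.approx(0.652, rel=0.025)

    def test_kH_cc_consistent_with_ideal_gas(self):
        assert K.kH_cc / K.kH_cp == pytest.approx(R_GAS_L_ATM * kelvin(25.0), rel=1e-2)


class TestBonding:
    @pytest.mark.parametrize(
        "phi,expected", [(2.0, 0.611), (4.0, 1.222)]
    )
    def test_absorbed_concentration_bounds(self, phi, expected):
        bonded = bonded_concentrations(BondingModel.from_phi(phi))
        assert bonded["absorbed"] == pytest.approx(expected, abs=5e-4)

    def test_no_enhancement_reduces_to_physical_difference(self):
        with pytest.warns(UserWarning):
            bond = BondingModel.from_phi(1.0)
        bonded = bonded_concentrations(bond)
        expected = henry_dissolved_concentration(K.p_O2_artery) - henry_dissolved_concentration(K.p_O2_vein)
        assert bonded["absorbed"] == pytest.approx(expected, rel=1e-12)

    def test_fully_dissociated_vein_keeps_physical_value(self):
        bonded = bonded_concentrations(BondingModel.from_phi(2.0), venous_dissociated=True)
        assert bonded["vein"] == pytest.approx(0.0753, rel=1e-3)

    def test_x_to_phi_worked_value(self):
        assert BondingModel.from_x(0.553).phi == pytest.approx(2.24, abs=0.01)

    @pytest.mark.parametrize("phi,x", [(4.0, 0.75), (2.0, 0.5)])
    def test_phi_to_x(self, phi, x):
        assert BondingModel.from_phi(phi).X == pytest.approx(x, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0.0, 0.99))
    def test_round_trip_x_phi_x(self, x):
        assert BondingModel.from_phi(BondingModel.from_x(x).phi).X == pytest.approx(
            x, abs=1e-12
        )

    def test_invalid_phi_raises(self):
        with pytest.raises(ValueError):
            BondingModel.from_phi(-1.0)


class TestHeartRate:
    def test_range_brackets_printed_bounds(self):
        v = float(molar_to_volumetric(1.04e-10))
        assert v == pytest.approx(1.395e-7, rel=5e-3)
        heart = HeartModel()
        assert heart.V_ventricle_l == pytest.approx(4.25e-6)
        assert heart_rate(v, 1.222, heart) == pytest.approx(2.7, abs=0.05)
        assert heart_rate(v, 0.611, heart) == pytest.approx(5.4, abs=0.05)

    def test_doubling_ventricle_halves_rate(self):
        v = float(molar_to_volumetric(1.04e-10))
        small = HeartModel(V_heart=8.5e-9)
        big = HeartModel(V_heart=1.7e-8)
        assert heart_rate(v, 1.0, big) == pytest.approx(heart_rate(v, 1.0, small) / 2)

    def test_outlet_velocity_from_heart(self):
        u = outlet_velocity(4.8, HeartModel(), 3.5e-4)
        assert u == pytest.approx(0.0035, rel=0.02)


class TestFickSurface:
    def test_worked_surface_value(self):
        # area-weighted membrane thickness of the calibrated geometry
        assert diffusive_surface_fick(1.04e-10, 77.6e-6) * 1e6 == pytest.approx(
            56.2, rel=0.01
        )

    def test_zero_rate_gives_zero(self):
        assert diffusive_surface_fick(0.0, 77.6e-6) == 0.0

    def test_agrees_with_geometric_surface(self):
        fick = diffusive_surface_fick(1.04e-10, 77.6e-6) * 1e6
        assert fick == pytest.approx(53.9, rel=0.05)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.floats(1e-12, 1e-9), d=st.floats(1e-5, 3e-4), s=st.floats(0.5, 2.0))
    def test_linear_in_rate_and_thickness(self, n, d, s):
        base = diffusive_surface_fick(n, d)
        assert diffusive_surface_fick(n * s, d) == pytest.approx(base * s, rel=1e-12)
        assert diffusive_surface_fick(n, d * s) == pytest.approx(base * s, rel=1e-12)


class TestOmegaMax:
    def test_prefactor(self):
        assert omega_max(1.0) == pytest.approx(8.7387e-6, rel=1e-3)

    def test_default_xi(self):
        assert omega_max(0.75) == pytest.approx(6.554e-6, rel=1e-3)

    def test_invalid_xi_raises(self):
        with pytest.raises(ValueError):
            omega_max(0.0)


class TestDissolvedCheck:
    def test_printed_operands_reproduce_worked_values(self):
        # the consistency check is defined on the rounded turnover and
        # hemolymph flow (1.4e-7 and 2e-5 l/min)
        c = dissolved_concentration(1.4e-7, 2e-5)
        assert c == pytest.approx(0.7, rel=1e-12)
        assert c / 0.65 == pytest.approx(1.077, abs=5e-4)

    def test_exact_chain_agrees_within_rounding(self):
        out = dissolved_check(1.04e-10, 4.8)
        assert out["c_dissolved"] == pytest.approx(0.7, rel=0.03)
        assert out["enhancement_ratio"] == pytest.approx(1.077, rel=0.03)

    def test_upper_uncertainty_raises_ratio(self):
        out = dissolved_check(1.29e-10, 4.8)
        assert out["enhancement_ratio"] == pytest.approx(1.34, rel=0.03)

    def test_zero_consumption(self):
        out = dissolved_check(0.0, 4.8)
        assert out == {"c_dissolved": 0.0, "enhancement_ratio": 0.0}
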