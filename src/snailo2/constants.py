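"""Physical constants for the hemolymph oxygen-transport model.

All defaults are the values used throughout the *Xeropicta derbentina*
lung model: Henry constant for O2 in water, diffusivities of O2 in
water/hemolymph and in pulmonary tissue, venous and arterial O2 partial
pressures (measured in *Helix pomatia*, adopted for *X. derbentina*),
and water properties at 25 degC standing in for hemolymph.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Universal gas constant, l atm mol-1 K-1 (for Henry-constant conversions).
R_GAS_L_ATM = 0.0820574

CELSIUS_OFFSET = 273.15


def kelvin(temp_c: float) -> float:
    """Convert a temperature from degC to K."""
    return temp_c + CELSIUS_OFFSET


@dataclass(frozen=True)
class PhysicalConstants:
    """Printed physical constants of the oxygen budget and transport model.

    Attributes
    ----------
    kH_cp : float
        Henry constant for O2 in water, mol l-1 atm-1 (concentration per
        partial pressure form).
    M_O2 : float
        Molar mass of O2, g mol-1.
    rho_O2_gas : float
        Density of gaseous O2 at 25 degC and 1 atm, g l-1.
    rho_H2O : float
        Density of water (hemolymph surrogate), kg m-3.
    mu_water : float
        Dynamic viscosity of water at 25 degC, Pa s.
    D1 : float
        Diffusivity of O2 in water/hemolymph, m2 s-1.
    D2 : float
        Diffusivity of O2 in pulmonary tissue, m2 s-1.
    p_O2_vein, p_O2_artery : float
        Venous and arterial O2 partial pressures, Pa.
    r_O2_ambient : float
        Ambient O2 mole (volume) fraction.
    p_atm : float
        Atmospheric pressure, Pa.
    V_standard_molar : float
        Molar volume of an ideal gas at standard conditions, l mol-1.
    temp_C : float
        Reference temperature for the water/gas properties, degC.
    """

    kH_cp: float = 1.3e-3
    M_O2: float = 31.9988
    rho_O2_gas: float = 1.308
    rho_H2O: float = 997.0
    mu_water: float = 8.94e-4
    D1: float = 2.1e-9
    D2: float = 2.3e-9
    p_O2_vein: float = 2399.8
    p_O2_artery: float = 12132.3
    r_O2_ambient: float = 0.2095
    p_atm: float = 101325.0
    V_standard_molar: float = 22.414
    temp_C: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "kH_cp", "M_O2", "rho_O2_gas", "rho_H2O", "mu_water",
            "D1", "D2", "p_O2_vein", "p_O2_artery", "r_O2_ambient",
            "p_atm", "V_standard_molar",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kH_cc(self) -> float:
        """Dimensionless Henry constant (aqueous/gas concentration ratio).

        Derived from ``kH_cp`` via the ideal-gas law at the reference
        temperature; about 0.0318 at 25 degC.
        """
        return self.kH_cp * R_GAS_L_ATM * kelvin(self.temp_C)

    @property
    def kH_cp_SI(self) -> float:
        """Henry constant in SI units, mol m-3 Pa-1."""
        return self.kH_cp * 1e3 / self.p_atm

    @property
    def nu_water(self) -> float:
        """Kinematic viscosity of water, m2 s-1."""
        return self.mu_water / self.rho_H2O


#: Module-wide default constants (water at 25 degC).
DEFAULT_CONSTANTS = PhysicalConstants()
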