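"""Henry's-law oxygen budget of the hemolymph.

Dissolved O2 concentrations in vein and artery follow from the measured
partial pressures and the Henry constant for O2 in water; hemocyanin
raises the carrying capacity by a lumped factor Phi (2-4). Closing the
budget against the measured consumption rate yields the heart-rate
range, the Fick's-law diffusive surface of the lung, and the
dissolved-oxygen consistency checks.

Concentrations are handled internally as dimensionless volume fractions
and reported in the conventional ml per 100 ml unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "BondingModel",
    "HeartModel",
    "henry_dissolved_concentration",
    "ambient_saturation",
    "bonded_concentrations",
    "molar_to_volumetric",
    "heart_rate",
    "outlet_velocity",
    "diffusive_surface_fick",
    "omega_max",
    "dissolved_concentration",
    "dissolved_check",
    "budget_report",
]

#: Literature physical solubility of ambient O2 in water at 25 degC,
#: ml per 100 ml (used by the consistency checks).
LITERATURE_SOLUBILITY = 0.65


@dataclass(frozen=True)
class BondingModel:
    """Lumped hemocyanin enhancement.

    ``phi`` multiplies the dissolved concentration (2-4 for molluscan
    hemocyanin); ``X = (phi - 1)/phi`` is the fraction of transferred O2
    that passes from physical solution into the chemical bond.
    """

    phi: float
    X: float

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not 0 <= self.X < 1:
            raise ValueError("X must lie in [0, 1)")
        if abs(self.X - (self.phi - 1.0) / self.phi) > 1e-9:
            raise ValueError("inconsistent phi and X: X must equal (phi-1)/phi")
        if not 2.0 <= self.phi <= 4.0:
            warnings.warn("phi outside the hemocyanin range 2-4", stacklevel=3)

    @classmethod
    def from_phi(cls, phi: float) -> "BondingModel":
        if phi <= 0:
            raise ValueError("phi must be positive")
        return cls(phi=phi, X=(phi - 1.0) / phi)

    @classmethod
    def from_x(cls, x: float) -> "BondingModel":
        if not 0 <= x < 1:
            raise ValueError("X must lie in [0, 1)")
        return cls(phi=1.0 / (1.0 - x), X=x)


@dataclass(frozen=True)
class HeartModel:
    """Heart geometry: total volume and the ventricle (stroke) fraction."""

    V_heart: float = 8.5e-9          # m3
    ventricle_fraction: float = 0.5  # conservative stroke fraction

    def __post_init__(self) -> None:
        if self.V_heart <= 0 or not 0 < self.ventricle_fraction <= 1:
            raise ValueError("invalid heart geometry")

    @property
    def V_ventricle(self) -> float:
        """Ventricle volume, m3."""
        return self.ventricle_fraction * self.V_heart

    @property
    def V_ventricle_l(self) -> float:
        """Ventricle volume, l."""
        return self.V_ventricle * 1e3


def henry_dissolved_concentration(p_o2, k: PhysicalConstants = DEFAULT_CONSTANTS):
    """Dissolved O2 from Henry's law, in ml per 100 ml.

    ``c = kH_cp * (p/p_atm) * M_O2 / rho_O2_gas``; linear in the partial
    pressure. 2399.8 Pa (vein) gives 0.0753 and 12132.3 Pa (artery)
    0.381 ml/100ml.
    """
    p = np.asarray(p_o2, float)
    if np.any(p < 0):
        raise ValueError("p_o2 must be non-negative")
    frac = k.kH_cp * (p / k.p_atm) * k.M_O2 / k.rho_O2_gas  # l O2 per l
    out = frac * 100.0
    return out if out.ndim else float(out)


def ambient_saturation(k: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Physical solubility of ambient O2 (20.95%), ml per 100 ml (0.666)."""
    return k.kH_cc * k.r_O2_ambient * 100.0


def bonded_concentrations(
    bond: BondingModel,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
    venous_dissociated: bool = False,
) -> dict:
    """Arterial, venous and absorbed concentrations with hemocyanin bonding.

    artery = phi * dissolved(p_artery); vein = phi * dissolved(p_vein)
    unless the venous hemocyanin is taken as fully dissociated, in which
    case the vein holds only the physically dissolved 0.0753 ml/100ml.
    absorbed = artery - vein. All values in ml per 100 ml.
    """
    c_vein_phys = henry_dissolved_concentration(k.p_O2_vein, k)
    c_artery_phys = henry_dissolved_concentration(k.p_O2_artery, k)
    artery = bond.phi * c_artery_phys
    vein = c_vein_phys if venous_dissociated else bond.phi * c_vein_phys
    return {"artery": artery, "vein": vein, "absorbed": artery - vein}


def molar_to_volumetric(n_dot, k: PhysicalConstants = DEFAULT_CONSTANTS):
    """Convert an O2 rate from mol s-1 to l min-1 at standard molar volume."""
    return np.asarray(n_dot, float) * 60.0 * k.V_standard_molar


def heart_rate(v_dot_o2: float, c_absorbed: float, heart: HeartModel) -> float:
    """Heart rate (min-1) closing the O2 budget.

    Parameters
    ----------
    v_dot_o2 : float
        Consumed O2 as a volume flow, l min-1.
    c_absorbed : float
        Absorbed concentration, ml per 100 ml.
    heart : HeartModel
        Supplies the stroke (ventricle) volume.
    """
    if v_dot_o2 <= 0 or c_absorbed <= 0:
        raise ValueError("rate and concentration must be positive")
    return v_dot_o2 / ((c_absorbed / 100.0) * heart.V_ventricle_l)


def outlet_velocity(f: float, heart: HeartModel, d_main_vein: float) -> float:
    """Mean main-vein outlet velocity (m s-1) driven by the heart.

    The stroke volume times the heart rate gives the hemolymph volume
    flow; dividing by the main-vein cross-section yields the velocity
    (0.0035 m s-1 at f = 4.8 min-1).
    """
    q = heart.V_ventricle * f / 60.0  # m3 s-1
    return q / (np.pi / 4.0 * d_main_vein**2)


def diffusive_surface_fick(
    n_dot: float,
    d_membrane_av: float,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
    delta_p: float | None = None,
) -> float:
    """Active diffusive surface (m2) from Fick's first law.

    ``A = n_dot * d_av / (D2 * kH_cp_SI * delta_p)`` with the
    venous-arterial mean pressure difference
    ``delta_p = (p_artery - p_vein)/2`` by default, because the venous
    O2 pressure rises continually along the vein and only starts at the
    printed venous value.
    """
    if delta_p is None:
        delta_p = (k.p_O2_artery - k.p_O2_vein) / 2.0
    return n_dot * d_membrane_av / (k.D2 * k.kH_cp_SI * delta_p)


def omega_max(xi: float, k: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Saturation O2 mass fraction in the lung-adjacent hemolymph.

    ``omega_max = xi * kH_cp * p_O2_ambient * M_O2 / rho_H2O`` (a
    dimensionless mass fraction, prefactor 8.74e-6). ``xi`` in (0, 1]
    accounts for the reduced O2 level inside the lung; 0.6-0.75 is the
    physiological band, 0.75 the default.
    """
    if not 0 < xi <= 1:
        raise ValueError("xi must lie in (0, 1]")
    c_molar = k.kH_cp * 1e3 * k.r_O2_ambient          # mol m-3 at 1 atm total
    return xi * c_molar * (k.M_O2 * 1e-3) / k.rho_H2O


def dissolved_concentration(v_dot_o2: float, v_flow: float) -> float:
    """Dissolved O2 per volume of hemolymph, ml per 100 ml.

    Ratio of the volumetric O2 uptake (l min-1) to the hemolymph volume
    flow (l min-1), expressed per 100 ml.
    """
    if v_flow <= 0:
        raise ValueError("hemolymph flow must be positive")
    return v_dot_o2 / v_flow * 100.0


def dissolved_check(
    n_dot_measured: float,
    f: float,
    heart: HeartModel = HeartModel(),
    k: PhysicalConstants = DEFAULT_CONSTANTS,
    literature_solubility: float = LITERATURE_SOLUBILITY,
) -> dict:
    """Consistency check: dissolved concentration and hemocyanin enhancement.

    Relates the measured O2 turnover (mol s-1) at heart rate ``f``
    (min-1) to the hemolymph volume flow; the enhancement ratio compares
    the result with the physical solubility of O2 in water at 25 degC.
    """
    if n_dot_measured == 0:
        return {"c_dissolved": 0.0, "enhancement_ratio": 0.0}
    v_dot = float(molar_to_volumetric(n_dot_measured, k))     # l min-1
    v_flow = heart.V_ventricle_l * f                          # l min-1
    c = dissolved_concentration(v_dot, v_flow)
    return {"c_dissolved": c, "enhancement_ratio": c / literature_solubility}


def budget_report(
    n_dot_measured: float = 1.04e-10,
    heart: HeartModel = HeartModel(),
    k: PhysicalConstants = DEFAULT_CONSTANTS,
    xi: float = 0.75,
) -> dict:
    """All oxygen-budget quantities as one flat dictionary."""
    phi2 = bonded_concentrations(BondingModel.from_phi(2.0), k)
    phi4 = bonded_concentrations(BondingModel.from_phi(4.0), k)
    v_dot = float(molar_to_volumetric(n_dot_measured, k))
    return {
        "c_vein_phys_ml_100ml": henry_dissolved_concentration(k.p_O2_vein, k),
        "c_artery_phys_ml_100ml": henry_dissolved_concentration(k.p_O2_artery, k),
        "c_ambient_ml_100ml": ambient_saturation(k),
        "c_absorbed_min_ml_100ml": phi2["absorbed"],
        "c_absorbed_max_ml_100ml": phi4["absorbed"],
        "v_dot_o2_l_min": v_dot,
        "heart_rate_min_per_min": heart_rate(v_dot, phi4["absorbed"], heart),
        "heart_rate_max_per_min": heart_rate(v_dot, phi2["absorbed"], heart),
        "omega_max": omega_max(xi, k),
        "V_ventricle_l": heart.V_ventricle_l,
    }
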