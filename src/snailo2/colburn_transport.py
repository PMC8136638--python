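"""Colburn-analogy segment marching along the vein network.

Oxygen crosses the vessel wall by Fick diffusion
(``j = rho*D2*(omega_max - omega_w)/dy``) and enters the bulk hemolymph
by convective mass transfer. The Colburn analogy
``Sh = (c_f/2)*Re*Sc**(1/3)`` links the convective transfer coefficient
to the wall shear stress of the laminar flow; for a short segment
(flat-plate limit) the characteristic length cancels, leaving

    j_w = (D1/nu)**(2/3) * (omega_w - omega_2) * tau_w/u_inf.

The wall mass fraction ``omega_w`` is closed by flux continuity: the
mass flow through the membrane (Fick, area ``A_mean``) equals the mass
flow into the bulk (Colburn, area ``A_inner``), giving a closed-form
segment solution. Each capillary (40 segments) and the main vein
(240 segments) are then marched downstream: the dissolved fraction of
segment i is the accumulated diffusion mass flow upstream of i, reduced
by the hemocyanin bonding fraction X, divided by the local hemolymph
mass flow, and clamped at the saturation value ``omega_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .hemodynamics import FlowState, solve_network_flow, wall_shear_to_velocity_ratio
from .oxygen_budget import BondingModel, omega_max as _omega_max
from .vein_geometry import VeinNetwork, segment_areas

__all__ = [
    "TransportParams",
    "SegmentState",
    "CapillaryResult",
    "MainVeinResult",
    "TransportResult",
    "colburn_flux",
    "membrane_flux",
    "exchange_coefficients",
    "wall_mass_fraction",
    "segment_diffusion_flow",
    "march_capillary",
    "march_main_vein",
    "total_oxygen_flow",
    "run_transport",
    "transport_to_frame",
]


@dataclass(frozen=True)
class TransportParams:
    """Tunables of the transport model.

    xi : reduction of the ambient O2 level inside the lung (0.6-0.75,
    default 0.75). bonding : hemocyanin model, default X = 0.553
    (phi = 2.24). Fluid properties default to water at 25 degC.
    """

    xi: float = 0.75
    bonding: BondingModel = field(default_factory=lambda: BondingModel.from_x(0.553))
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not 0 < self.xi <= 1:
            raise ValueError("xi must lie in (0, 1]")

    @property
    def omega_max(self) -> float:
        """Saturation dissolved-O2 mass fraction in the lung-side hemolymph."""
        return _omega_max(self.xi, self.constants)

    @property
    def colburn_prefactor(self) -> float:
        """(D1/nu)**(2/3), about 0.0177 for O2 in water at 25 degC."""
        k = self.constants
        return (k.D1 / k.nu_water) ** (2.0 / 3.0)


@dataclass(frozen=True)
class SegmentState:
    """Transport state of one vessel segment."""

    omega_2: float   # dissolved mass fraction after bonding
    omega_w: float   # mass fraction at the inner wall
    omega_t: float   # total (dissolved + bound) mass fraction
    J: float         # segment diffusion mass flow, kg s-1
    m_dot: float     # hemolymph mass flow, kg s-1


def colburn_flux(omega_w: float, omega_2: float, tau_over_u: float,
                 p: TransportParams) -> float:
    """Convective wall mass flux (kg m-2 s-1) from the Colburn analogy."""
    return p.colburn_prefactor * (omega_w - omega_2) * tau_over_u


def membrane_flux(omega_w: float, thickness: float, p: TransportParams) -> float:
    """Fick mass flux through the vessel wall (kg m-2 s-1)."""
    k = p.constants
    return k.rho_H2O * k.D2 * (p.omega_max - omega_w) / thickness


def exchange_coefficients(
    diameter: float,
    membrane_thickness: float,
    dx: float,
    fraction: float,
    tau_over_u: float,
    p: TransportParams,
) -> tuple[float, float]:
    """Membrane and convective conductances (kg s-1 per unit d-omega).

    ``a = rho*D2*A_mean/dy`` drives the membrane (Fick) side through the
    mean-radius area; ``b = (D1/nu)**(2/3)*(tau_w/u)*A_inner`` the
    convective (Colburn) side through the inner wall area.
    """
    a_inner, a_mean = segment_areas(diameter, membrane_thickness, dx, fraction)
    k = p.constants
    a = k.rho_H2O * k.D2 * a_mean / membrane_thickness
    b = p.colburn_prefactor * tau_over_u * a_inner
    return a, b


def wall_mass_fraction(omega_2: float, a: float, b: float, p: TransportParams) -> float:
    """Wall mass fraction from flux continuity across the two areas.

    Solves a*(omega_max - omega_w) = b*(omega_w - omega_2):
    omega_w = (a*omega_max + b*omega_2)/(a + b). In the limit b >> a the
    transfer is membrane-limited and omega_w -> omega_2; at
    omega_2 = omega_max the segment is saturated and the flux vanishes.
    """
    return (a * p.omega_max + b * omega_2) / (a + b)


def segment_diffusion_flow(omega_w: float, a: float, p: TransportParams) -> float:
    """Segment diffusion mass flow J = a*(omega_max - omega_w), kg s-1."""
    return a * (p.omega_max - omega_w)


@dataclass(frozen=True)
class CapillaryResult:
    """Marched transport profile of one capillary."""

    index: int
    segments: tuple          # of SegmentState
    total_J: float           # kg s-1
    m_dot: float             # kg s-1 (constant along the capillary)

    @property
    def omega_2(self) -> np.ndarray:
        return np.array([s.omega_2 for s in self.segments])

    @property
    def omega_w(self) -> np.ndarray:
        return np.array([s.omega_w for s in self.segments])

    @property
    def omega_t(self) -> np.ndarray:
        return np.array([s.omega_t for s in self.segments])

    @property
    def J(self) -> np.ndarray:
        return np.array([s.J for s in self.segments])


@dataclass(frozen=True)
class MainVeinResult:
    """Marched transport profile of the main vein."""

    segments: tuple
    total_J: float

    @property
    def omega_2(self) -> np.ndarray:
        return np.array([s.omega_2 for s in self.segments])

    @property
    def omega_w(self) -> np.ndarray:
        return np.array([s.omega_w for s in self.segments])

    @property
    def omega_t(self) -> np.ndarray:
        return np.array([s.omega_t for s in self.segments])

    @property
    def J(self) -> np.ndarray:
        return np.array([s.J for s in self.segments])

    @property
    def m_dot(self) -> np.ndarray:
        return np.array([s.m_dot for s in self.segments])


@dataclass(frozen=True)
class TransportResult:
    """Complete transport solution and the total oxygen diffusion flow."""

    capillaries: tuple       # of CapillaryResult, in capillary order
    main_vein: MainVeinResult
    n_dot_total: float       # mol s-1
    total_mass_flow: float   # kg s-1


def march_capillary(
    capillary,
    u: float,
    p: TransportParams,
    fraction: float,
    k: PhysicalConstants | None = None,
) -> CapillaryResult:
    """March one capillary downstream (velocity and tau_w constant).

    Segment 1 starts at omega_2 = 0; every later segment relates the
    accumulated upstream diffusion mass flow (reduced by the bonded
    fraction X) to the capillary's hemolymph mass flow, clamped at
    omega_max.
    """
    k = k or p.constants
    tau_over_u = wall_shear_to_velocity_ratio(capillary.diameter, k)
    a, b = exchange_coefficients(
        capillary.diameter, capillary.membrane_thickness, capillary.dx,
        fraction, tau_over_u, p,
    )
    m_dot = k.rho_H2O * capillary.cross_section * u
    one_minus_x = 1.0 - p.bonding.X
    w_max = p.omega_max

    states = []
    j_sum = 0.0
    for _ in range(capillary.n_segments):
        omega_t = j_sum / m_dot
        omega_2 = min(one_minus_x * omega_t, w_max)
        omega_w = wall_mass_fraction(omega_2, a, b, p)
        j = segment_diffusion_flow(omega_w, a, p)
        states.append(SegmentState(omega_2, omega_w, omega_t, j, m_dot))
        j_sum += j
    return CapillaryResult(
        index=capillary.index, segments=tuple(states), total_J=j_sum, m_dot=m_dot
    )


def march_main_vein(
    net: VeinNetwork,
    flow: FlowState,
    capillary_results,
    p: TransportParams,
    k: PhysicalConstants | None = None,
) -> MainVeinResult:
    """March the main vein downstream, mixing in capillary inflows.

    The first segment is already premixed with the diffusion mass flow
    of the two front capillaries; each segment's velocity is the
    cumulative capillary volume flow over the main-vein cross-section.
    """
    k = k or p.constants
    mv = net.main_vein
    if len(capillary_results) != len(net.capillaries):
        raise ValueError("need one marched result per capillary")
    by_index = {c.index: c for c in capillary_results}

    # capillary diffusion mass flow entering at each junction
    j_cap_at_junction = np.array(
        [sum(by_index[i].total_J for i in caps) for caps in mv.junctions]
    )
    if j_cap_at_junction.size != mv.n_junctions:
        raise ValueError("junction bookkeeping mismatch")
    j_cap_cum = np.cumsum(j_cap_at_junction)

    tau_over_u = wall_shear_to_velocity_ratio(mv.diameter, k)
    a, b = exchange_coefficients(
        mv.diameter, mv.membrane_thickness, mv.dx,
        net.perimeter_fraction_transport, tau_over_u, p,
    )
    one_minus_x = 1.0 - p.bonding.X
    w_max = p.omega_max

    states = []
    j_sum_mv = 0.0
    for i in range(mv.n_segments):
        run = i // mv.segments_per_run
        u_i = flow.main_vein_velocity[i]
        m_dot = k.rho_H2O * mv.cross_section * u_i
        upstream_j = j_cap_cum[run] + j_sum_mv
        omega_t = upstream_j / m_dot
        omega_2 = min(one_minus_x * omega_t, w_max)
        omega_w = wall_mass_fraction(omega_2, a, b, p)
        j = segment_diffusion_flow(omega_w, a, p)
        states.append(SegmentState(omega_2, omega_w, omega_t, j, m_dot))
        j_sum_mv += j
    return MainVeinResult(segments=tuple(states), total_J=j_sum_mv)


def total_oxygen_flow(
    capillary_results,
    main_vein_result: MainVeinResult,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Total oxygen diffusion flow of the vein system, mol s-1."""
    total = sum(c.total_J for c in capillary_results) + main_vein_result.total_J
    return total / (k.M_O2 * 1e-3)


def run_transport(
    net: VeinNetwork,
    p: TransportParams | None = None,
    flow: FlowState | None = None,
    u_outlet: float = 0.0035,
) -> TransportResult:
    """Flow solve plus full capillary and main-vein marching."""
    p = p or TransportParams()
    k = p.constants
    if flow is None:
        flow = solve_network_flow(net, u_outlet=u_outlet, k=k)
    caps = tuple(
        march_capillary(
            c, flow.capillary_velocity[c.index - 1], p,
            net.perimeter_fraction_transport, k,
        )
        for c in net.capillaries
    )
    mv = march_main_vein(net, flow, caps, p, k)
    total_mass = sum(c.total_J for c in caps) + mv.total_J
    return TransportResult(
        capillaries=caps,
        main_vein=mv,
        n_dot_total=total_mass / (k.M_O2 * 1e-3),
        total_mass_flow=total_mass,
    )


def transport_to_frame(result: TransportResult) -> pd.DataFrame:
    """Per-segment table (vessel, segment, omega_2, omega_w, omega_t, J)."""
    rows = []
    for c in result.capillaries:
        for s_id, s in enumerate(c.segments, start=1):
            rows.append(
                ("capillary_%d" % c.index, s_id, s.omega_2, s.omega_w, s.omega_t, s.J)
            )
    for s_id, s in enumerate(result.main_vein.segments, start=1):
        rows.append(("main_vein", s_id, s.omega_2, s.omega_w, s.omega_t, s.J))
    return pd.DataFrame(
        rows, columns=["vessel", "segment", "omega_2", "omega_w", "omega_t", "J_kg_s"]
    )
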