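"""Laminar Hagen-Poiseuille flow through the vein network.

At Re ~ 1 the flow in every vessel is fully developed laminar pipe
flow, so the network reduces to a linear resistance tree: every branch
has resistance 128*mu*L/(pi*d**4), all capillary inlets sit at the same
(ambient) pressure, and the total outlet flow is prescribed by the
heart. Because the network is a tree fed from a common pressure, the
solution is a single downstream marching pass plus one linear scaling
to the prescribed outlet flow. Wall shear stress follows from the
fully developed ratio tau_w/u = 8*mu/d.

Water properties stand in for hemolymph throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .vein_geometry import VeinNetwork

__all__ = [
    "FlowState",
    "wall_shear_to_velocity_ratio",
    "pressure_loss",
    "reynolds_number",
    "solve_network_flow",
    "quadratic_tau_fit",
    "flow_to_frame",
]

RE_LAMINAR_LIMIT = 2300.0


def wall_shear_to_velocity_ratio(d: float, k: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Fully developed ratio tau_w/u_mean = 8*mu/d, Pa s m-1.

    47.7 for the 0.15 mm capillaries and 20.3 for the 0.35 mm main vein
    with water at 25 degC.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    return 8.0 * k.mu_water / d


def reynolds_number(u: float, d: float, k: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Pipe Reynolds number u*d/nu."""
    return u * d / k.nu_water


def pressure_loss(length: float, d: float, u: float,
                  k: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Laminar (64/Re) pressure loss 32*mu*L*u/d**2, Pa; linear in u and L."""
    re = reynolds_number(u, d, k)
    if re > RE_LAMINAR_LIMIT:
        warnings.warn(f"Re = {re:.0f} exceeds the laminar limit", stacklevel=2)
    return 32.0 * length * k.mu_water * u / d**2


@dataclass(frozen=True)
class FlowState:
    """Resolved network flow: velocities, flows and wall shear stresses.

    Capillary arrays are indexed by capillary number - 1 (order 1..37);
    main-vein arrays by segment (240 entries). ``run_flow`` holds the
    cumulative volume flow in each inter-junction run (24 entries).
    """

    capillary_velocity: np.ndarray      # m s-1, per capillary
    capillary_flow: np.ndarray          # m3 s-1, per capillary
    tau_w_capillary: np.ndarray         # Pa, per capillary
    main_vein_velocity: np.ndarray      # m s-1, per segment
    tau_w_main_vein: np.ndarray         # Pa, per segment
    run_flow: np.ndarray                # m3 s-1, per inter-junction run
    u_outlet: float                     # m s-1
    reynolds_outlet: float

    def __post_init__(self) -> None:
        if np.any(self.capillary_velocity <= 0) or np.any(self.main_vein_velocity <= 0):
            raise ValueError("all velocities must be positive")
        if np.any(np.diff(self.main_vein_velocity) < -1e-15):
            raise ValueError("main-vein velocity must be non-decreasing downstream")
        if self.reynolds_outlet >= RE_LAMINAR_LIMIT:
            raise ValueError("flow is not laminar")


def solve_network_flow(
    net: VeinNetwork,
    u_outlet: float = 0.0035,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
) -> FlowState:
    """Solve the resistance-tree flow for a prescribed outlet velocity.

    All capillary inlets share the ambient pressure; the outlet volume
    flow is ``u_outlet`` times the main-vein cross-section. Junction
    pressure differences are marched distal to proximal (linear in one
    unknown scale, fixed by the outlet flow), which makes downstream
    capillaries carry more flow than upstream ones — the suction from
    the heart is felt more strongly near the outlet.
    """
    if u_outlet <= 0:
        raise ValueError("u_outlet must be positive")
    mv = net.main_vein
    njunc = mv.n_junctions
    run_length = mv.length / njunc
    r_run = 128.0 * k.mu_water * run_length / (np.pi * mv.diameter**4)

    caps_by_junction = mv.junctions
    r_cap = [
        [
            128.0 * k.mu_water * net.capillaries[i - 1].length
            / (np.pi * net.capillaries[i - 1].diameter**4)
            for i in caps
        ]
        for caps in caps_by_junction
    ]

    # march in the unknown inlet-to-junction pressure difference x_1 = 1
    x = np.zeros(njunc)
    x[0] = 1.0
    q_branch = [None] * njunc
    run_flow = np.zeros(njunc)
    for j in range(njunc):
        q_branch[j] = [x[j] / r for r in r_cap[j]]
        run_flow[j] = (run_flow[j - 1] if j else 0.0) + sum(q_branch[j])
        if j + 1 < njunc:
            x[j + 1] = x[j] + r_run * run_flow[j]
    if run_flow[-1] <= 0:
        raise ValueError("singular network: no conducting path to the outlet")

    q_target = u_outlet * mv.cross_section
    scale = q_target / run_flow[-1]
    run_flow *= scale

    cap_flow = np.zeros(len(net.capillaries))
    for j, caps in enumerate(caps_by_junction):
        for i, q in zip(caps, q_branch[j]):
            cap_flow[i - 1] = q * scale
    cap_u = cap_flow / np.array([c.cross_section for c in net.capillaries])
    tau_cap = np.array(
        [wall_shear_to_velocity_ratio(c.diameter, k) for c in net.capillaries]
    ) * cap_u

    seg_run = np.arange(mv.n_segments) // mv.segments_per_run
    mv_u = run_flow[seg_run] / mv.cross_section
    tau_mv = wall_shear_to_velocity_ratio(mv.diameter, k) * mv_u

    return FlowState(
        capillary_velocity=cap_u,
        capillary_flow=cap_flow,
        tau_w_capillary=tau_cap,
        main_vein_velocity=mv_u,
        tau_w_main_vein=tau_mv,
        run_flow=run_flow,
        u_outlet=u_outlet,
        reynolds_outlet=reynolds_number(u_outlet, mv.diameter, k),
    )


def quadratic_tau_fit(values, positions) -> np.ndarray:
    """Exact interpolating quadratic through three (position, value) pairs.

    Returns coefficients (c0, c1, c2) of c0 + c1*x + c2*x**2. Used to
    approximate the wall-shear distribution along the main vein from
    its inlet, centre and outlet values.
    """
    x = np.asarray(positions, float)
    y = np.asarray(values, float)
    if x.size != 3 or y.size != 3:
        raise ValueError("need exactly three samples")
    if len(set(x.tolist())) != 3:
        raise ValueError("positions must be distinct")
    return np.linalg.solve(np.vander(x, 3, increasing=True), y)


def flow_to_frame(net: VeinNetwork, flow: FlowState) -> pd.DataFrame:
    """Per-segment table (vessel, segment id, position, u, tau_w) for export."""
    rows = []
    for c in net.capillaries:
        u = flow.capillary_velocity[c.index - 1]
        tau = flow.tau_w_capillary[c.index - 1]
        for s in range(c.n_segments):
            rows.append(
                ("capillary_%d" % c.index, s + 1, (s + 0.5) * c.dx, u, tau)
            )
    mv = net.main_vein
    for s in range(mv.n_segments):
        rows.append(
            (
                "main_vein",
                s + 1,
                (s + 0.5) * mv.dx,
                flow.main_vein_velocity[s],
                flow.tau_w_main_vein[s],
            )
        )
    return pd.DataFrame(rows, columns=["vessel", "segment", "position_m", "u_m_s", "tau_w_pa"])
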