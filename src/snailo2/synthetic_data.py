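"""Synthetic inputs with known ground truth.

Generators for every input the pipeline consumes: closed-chamber
respirometry traces (linear O2 decline from a true consumption rate,
plus sensor temperature drift and Gaussian noise), allometric cohorts
(power-law rates with multiplicative lognormal scatter, shell masses
from the cubic shell model), and geometric perturbations of the vein
network for sensitivity scans. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .allometry import ShellModel, SpecimenRecord
from .constants import R_GAS, kelvin
from .respirometry import RespirometryTrace, dry_pressure
from .vein_geometry import Capillary, MainVein, VeinNetwork

__all__ = [
    "TraceSpec",
    "CohortSpec",
    "gen_respirometry_trace",
    "gen_cohort",
    "gen_perturbed_network",
]

#: Relative-humidity band observed in the chamber (fraction).
RH_BAND = (0.25, 0.50)


@dataclass(frozen=True)
class TraceSpec:
    """Ground truth and noise model for one synthetic respirometry trace.

    The defaults emulate a dormant medium-sized snail at 25 degC: true
    rate 1.04e-10 mol s-1 in a 20 ml chamber over 6 h, sensor noise at
    half the 0.01 %O2 resolution, and a linear sensor response to
    casing temperature (only the Pearson correlation of that drift was
    ever quantified, so the slope here is a generator parameter).
    """

    seed: int = 0
    true_rate: float = 1.04e-10       # mol s-1
    chamber_volume: float = 2e-5      # m3
    duration: float = 21600.0         # s
    dt: float = 30.0                  # s
    temp_c: float = 25.0              # degC, chamber temperature (water bath)
    temp_amplitude: float = 0.0       # degC, sinusoidal casing-temperature swing
    drift_slope: float = -0.02        # %O2 per degC
    noise_sd: float = 0.005           # %O2
    p_total: float = 101325.0         # Pa
    rel_humidity: float | None = None # draw from RH_BAND when None

    def __post_init__(self) -> None:
        if self.true_rate < 0 or self.chamber_volume <= 0 or self.dt <= 0:
            raise ValueError("invalid trace spec")


def gen_respirometry_trace(spec: TraceSpec) -> RespirometryTrace:
    """Synthesize a chamber trace consistent with the gas accounting.

    The mole series declines linearly at the true rate; the ideal-gas
    chain is inverted to the %O2 the sensor would read, and drift plus
    noise are added on the sensor scale.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    rh = (
        rng.uniform(*RH_BAND) if spec.rel_humidity is None else spec.rel_humidity
    )
    casing_temp = spec.temp_c + spec.temp_amplitude * np.sin(
        2 * np.pi * t / max(spec.duration, spec.dt)
    )
    # sealed chamber conditioned by the water bath: the dry gas amount is
    # fixed at the bath state and the O2 mole fraction declines linearly;
    # temperature excursions act on the sensor casing (drift), not on the
    # gas inventory
    p_dry0 = dry_pressure(spec.p_total, rh, spec.temp_c)
    n_total = p_dry0 * spec.chamber_volume / (R_GAS * kelvin(spec.temp_c))
    n_o2 = 0.2095 * n_total - spec.true_rate * t
    if np.any(n_o2 < 0):
        raise ValueError("trace spec depletes the chamber oxygen entirely")
    o2_percent = 100.0 * n_o2 / n_total
    o2_percent = o2_percent + spec.drift_slope * (casing_temp - spec.temp_c)
    if spec.noise_sd > 0:
        o2_percent = o2_percent + rng.normal(0.0, spec.noise_sd, t.size)
    return RespirometryTrace(
        t=t,
        o2_percent=o2_percent,
        p_total=spec.p_total,
        temp=spec.temp_c,
        rel_humidity=rh,
        chamber_volume=spec.chamber_volume,
        casing_temp=casing_temp,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Ground truth for a synthetic allometric cohort.

    Shell-free masses are uniform on ``mass_range`` (defaults span the
    0.65-1.25 cm shell-diameter groups); rates follow
    ``b * m**alpha * exp(eps)`` with lognormal scatter. Defaults are the
    25 degC dormant-cohort fit (alpha = 1.221, b = 2.835e-13).
    """

    seed: int = 0
    n: int = 25
    mass_range: tuple = (6e-5, 2e-4)      # kg, shell-free
    alpha: float = 1.221
    b: float = 2.835e-13                  # mol s-1 kg^-alpha
    noise_sd: float = 0.3                 # lognormal sigma on the rate
    temp_c: float = 25.0
    shell: ShellModel = field(default_factory=ShellModel)
    soft_tissue_density_coeff: float = 102.0  # kg m-3: m_soft ~ coeff * d**3

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.mass_range[0] <= 0 or self.mass_range[0] >= self.mass_range[1]:
            raise ValueError("invalid mass range")


def gen_cohort(spec: CohortSpec) -> list[SpecimenRecord]:
    """Generate a cohort of specimens with known scaling parameters."""
    rng = np.random.default_rng(spec.seed)
    m_soft = rng.uniform(*spec.mass_range, spec.n)
    diameter = (m_soft / spec.soft_tissue_density_coeff) ** (1.0 / 3.0)
    shell_mass = np.asarray(spec.shell.shell_mass(diameter), float)
    eps = rng.normal(0.0, spec.noise_sd, spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    rate = spec.b * m_soft**spec.alpha * np.exp(eps)
    return [
        SpecimenRecord(
            total_mass=float(m_soft[i] + shell_mass[i]),
            shell_diameter=float(diameter[i]),
            shell_free_mass=float(m_soft[i]),
            temp=spec.temp_c,
            o2_rate=float(rate[i]),
        )
        for i in range(spec.n)
    ]


def gen_perturbed_network(
    base: VeinNetwork,
    seed: int = 0,
    length_jitter: float = 0.05,
    diameter_jitter: float = 0.0,
) -> VeinNetwork:
    """Jitter vessel lengths/diameters by lognormal factors.

    Supports sensitivity scans around the calibrated geometry; all
    structural invariants (37 capillaries, junction table, segment
    counts) are preserved. Jitter fractions are lognormal sigmas and
    must stay below 0.5.
    """
    if not (0 <= length_jitter < 0.5 and 0 <= diameter_jitter < 0.5):
        raise ValueError("jitter fractions must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    def factor(sigma):
        return float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0

    capillaries = tuple(
        dataclasses.replace(
            c,
            length=c.length * factor(length_jitter),
            diameter=c.diameter * factor(diameter_jitter),
        )
        for c in base.capillaries
    )
    main_vein = dataclasses.replace(
        base.main_vein,
        length=base.main_vein.length * factor(length_jitter),
        diameter=base.main_vein.diameter * factor(diameter_jitter),
    )
    return dataclasses.replace(base, capillaries=capillaries, main_vein=main_vein)
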