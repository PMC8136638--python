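# Methods

This note documents the model implemented by `snailo2`: its physical
assumptions, the parameters that matter, the numerical choices, and
what the synthetic-data generators do and do not emulate.

## Respirometry reduction

A closed aluminium chamber of volume `V` (a required configuration
value; the default 20 ml matches a purpose-built micro-respirometer for
~1 cm snails) holds one animal. The sensor reports the O₂ volume
percentage; pressure, chamber temperature and relative humidity are
recorded alongside. The reduction chain is

1. water-vapour removal: `p_dry = p_total − Φ·e(T)` with the Magnus
   approximation `e(T) = 611.2·exp(17.62·T/(243.12+T))` Pa, valid on
   (−45, 60) °C and accurate to a few per mille against steam-table
   values on 0–45 °C;
2. ideal-gas conversion: `n_O2 = r_O2·p_dry·V/(R·T)` with
   R = 8.314 J mol⁻¹ K⁻¹ and T in kelvin (offset 273.15);
3. rate extraction: ordinary least squares on the mole time series.
   OLS is chosen because the decline is linear in time for a constant
   consumer and it yields a standard error with no extra machinery. A
   non-monotone trace still returns a rate but is flagged through R².

The electrochemical sensor responds linearly to the temperature of its
outer casing. That drift is fitted on empty-chamber baselines (only its
Pearson correlation, r ≈ −0.86, was ever quantified for the real
instrument, so the slope is a configuration/generator parameter) and
subtracted before the reduction. The trace container therefore carries
two temperature channels: the bath-controlled chamber temperature used
in the gas accounting and the casing temperature driving drift; when a
casing record is absent the chamber temperature is used for both.

## Allometric scaling and the response surface

Cohort metabolic rates follow `MR = b·m^α` with shell-free mass m. The
default fit is nonlinear least squares on the original scale (the
closed-form log-log regression is available via `method="loglog"` and
seeds the NLS); R² is always computed on the original scale and 95%
confidence intervals come from the fit covariance with a t-quantile.
Shell mass is removed with a cubic shell-diameter model; the default
coefficient (90 kg m⁻³, i.e. ~0.09 g shell at 1 cm) gives a plausible
shell fraction and is configuration-exposed, since the true cubic fit
coefficients are not available.

The temperature×mass response surface is
`O₂(m,T) = A(m) + B(m)·T + C(m)·T²` with A, B, C quadratic in m. The
shipped coefficient set returns mol s⁻¹ **with m in kg and T in °C**:
this unit reading is a calibrated interpretation — it is the only one
under which the coefficients reproduce rates of order 10⁻¹⁰ mol s⁻¹ for
a 0.1 g snail and zero crossings near 18 °C and 42 °C. Because the
surface is quadratic in T at fixed m, every isobole is obtained
analytically from the quadratic formula; the zero-level roots are the
theoretical physiological limits. Over the measured cohort mass range
(0.06–0.2 g shell-free) the lower root stays in 15–20 °C (arousal band)
and the upper in 40–43 °C (heat-stress band). Below ~0.055 g the upper
root drifts past 43 °C — those masses lie outside the measured cohorts
and the bands are not asserted there.

## Henry's-law oxygen budget

Dissolved O₂ obeys `c = k_H,cp·p` with k_H,cp = 1.3·10⁻³ mol l⁻¹ atm⁻¹
for O₂ in water at 25 °C; hemolymph is treated as water throughout.
Concentrations are volume fractions internally and ml·100 ml⁻¹ at the
reporting boundary. Venous and arterial partial pressures (2399.8 and
12132.3 Pa, measured in *Helix pomatia* and adopted for
*X. derbentina*) give 0.0753 and 0.381 ml·100 ml⁻¹; the ambient-air
saturation 0.666 ml·100 ml⁻¹ agrees with the literature solubility
0.652 within 2.5%, validating the constants.

Hemocyanin raises carrying capacity by a lumped factor Φ ∈ [2, 4] (no
binding kinetics are modelled); the absorbed concentration
`Φ·(0.381 − 0.0753)` spans 0.611–1.222 ml·100 ml⁻¹. Closing the budget
against the measured rate 1.04·10⁻¹⁰ mol s⁻¹ — converted with the
standard molar volume 22.414 l mol⁻¹ to 1.3986·10⁻⁷ l min⁻¹ — with a
ventricle of 4.25·10⁻⁶ l (50% of the 8.5 mm³ heart) yields heart rates
of 2.69–5.39 min⁻¹.

The Fick's-law diffusive surface uses
`A = ṅ·d_av/(D₂·k_H,cp·Δp)` with Δp the venous–arterial **mean**
difference (p_artery − p_vein)/2, because the venous O₂ pressure holds
its printed value only at the start of the vein and rises continually;
`d_av` is the wall-area-weighted mean membrane thickness (77.6 µm for
the default geometry). The result, 56.2 mm², agrees with the geometric
surface 53.9 mm² within 5%.

The dissolved-oxygen consistency check divides the volumetric O₂
turnover by the hemolymph volume flow at a given heart rate. The
conventional worked values (0.7 ml·100 ml⁻¹; enhancement ratios 1.077
and 1.34 against the 0.65 ml·100 ml⁻¹ solubility) arise from
one-significant-figure operands (1.4·10⁻⁷ and 2·10⁻⁵ l min⁻¹); the
package computes the exact chain (0.686, 1.055, 1.308), which agrees
within that rounding.

A note on two printed constants adopted here in corrected form: the
volumetric rate that reproduces the 2.7–5.4 min⁻¹ heart-rate range is
1.395·10⁻⁷ l min⁻¹ (not 10⁻⁶), and the saturation mass fraction at
ξ = 0.75 is ξ·8.739·10⁻⁶ = 6.55·10⁻⁶ (not 6.56·10⁻⁵); both follow
directly from the stated inputs, and with the ×10 variants neither the
heart-rate range nor the transport total could be consistent with the
measured consumption.

## Vein-network geometry

The network is parametric, not image-derived: 37 capillaries
(⌀ 0.15 mm, wall 0.06 mm, 40 segments each) join the main vein
(⌀ 0.35 mm, wall 0.12 mm, 240 segments) at 13 pairwise junctions
(capillaries 1/2 … 25/26, the first pair premixed at the distal front)
followed by 11 single junctions (capillaries 27–37), ten main-vein
segments between consecutive inflows. Vessel lengths are not published,
so uniform lengths are calibrated: the half-perimeter
(`perimeter_fraction_area = 0.5`, half-cylindrical contact with the
lung roof) surface must equal the 53.9 mm² CAD measurement, split
0.707/0.293 between capillaries and main vein — the only split whose
area-weighted membrane thickness (77.6 µm) closes the Fick's-law
surface at 56.2 mm². This gives 4.37 mm per capillary and a 28.7 mm
main vein. Both calibration targets are configuration-exposed. True
per-capillary length variation is unknown; uniformity is the declared
simplification.

Transport uses a slightly larger perimeter fraction (0.6) than the area
accounting (0.5) because the real vessel surfaces are uneven and
protrude into the lung lumen. Segment transfer areas distinguish the
inner wetted surface `A_inner = f·π·d·Δx` from the membrane-mean
surface `A_mean = f·π·(d+t)·Δx` (perimeter at the mean of inner and
outer wall radius — the standard flat-wall approximation for a curved
shell, in error by <3% for capillaries and <5% for the main vein).

## Hemodynamics

At Re ≈ 1.4 (outlet) the flow is deeply laminar and entrance lengths
are a few vessel diameters, so the network reduces to a linear
Hagen–Poiseuille resistance tree: branch resistance `128·μ·L/(π·d⁴)`,
all capillary inlets at ambient pressure, outlet volume flow prescribed
as `u_outlet·A_mv` with u_outlet = 0.0035 m s⁻¹ (the velocity a
4.8 min⁻¹ heart imposes through the 4.25 µl ventricle). No junction or
entrance minor losses are modelled. Because the tree hangs from one
common inlet pressure, the solution is a single distal-to-proximal
marching pass that is linear in one unknown, scaled to the outlet flow;
mass is conserved at every junction to round-off by construction.
Downstream capillaries feel the heart's suction more strongly and carry
more flow (ratio ≈ 9 between the fastest and slowest), and the
main-vein velocity rises monotonically to the outlet value with a
visible slope change where pairwise inflow gives way to single inflow.
Wall shear stress follows from the fully developed ratio
`τ_w/u∞ = 8μ/d`: 47.7 Pa s m⁻¹ (capillaries) and 20.3 Pa s m⁻¹ (main
vein) with μ = 8.94·10⁻⁴ Pa s (water, 25 °C). A helper fits the exact
interpolating quadratic through inlet/centre/outlet shear values for
profile summaries.

## Colburn-analogy transport

Within one short segment the mass-transfer problem approaches flow over
a flat plate with constant wall mass fraction, so the Colburn analogy
`Sh = (c_f/2)·Re·Sc^(1/3)` applies per segment. Substituting the
definitions and `c_f/2 = τ_w/(ρu²)` makes the characteristic length
cancel, leaving the wall flux

    j_w = (D₁/ν)^(2/3) · (ω_w − ω₂) · τ_w/u∞        [kg m⁻² s⁻¹]

with prefactor (D₁/ν)^⅔ ≈ 0.0177. The membrane side is Fick diffusion
`j = ρ·D₂·(ω_max − ω_w)/Δy`. The wall mass fraction ω_w is closed by
**flux continuity**: the mass flow through the membrane (through
A_mean) equals the mass flow into the bulk (through A_inner),

    a·(ω_max − ω_w) = b·(ω_w − ω₂),
    a = ρ·D₂·A_mean/Δy,   b = (D₁/ν)^(2/3)·(τ_w/u∞)·A_inner,

giving the closed form ω_w = (a·ω_max + b·ω₂)/(a+b). Continuity is the
only closure consistent with the marching step ordering; the transfer
is strongly membrane-limited (a/b ≈ 0.06 for capillaries), so ω_w sits
close to ω₂. Segment length enters only through the areas: the flux law
itself is length-free.

The saturation value is `ω_max = ξ·k_H,cp·p_O2,amb·M_O2/ρ_H2O =
ξ·8.74·10⁻⁶`, with ξ = 0.75 the default reduction of ambient O₂ inside
the lung (humidification, CO₂ enrichment; plausible band 0.6–0.75). The
hemocyanin buffer removes the fraction X = (Φ−1)/Φ of transferred
oxygen from physical solution; the default X = 0.553 (Φ = 2.24) is the
value consistent with the 4.8 min⁻¹ heart rate.

Marching (per capillary, 40 segments): segment 1 starts at ω₂ = 0; each
segment computes ω_w from the closure, its diffusion mass flow
`J = a·(ω_max − ω_w)`, and passes the running sum downstream:
`ω₂,i = (1−X)·Σ_{n<i} J_n / ṁ` (clamped at ω_max; a clamped segment
transfers nothing) and `ω_t,i = Σ_{n<i} J_n / ṁ` — ω_t includes bound
oxygen and is never clamped. Velocity and τ_w are constant along a
capillary. The main vein (240 segments) is marched the same way after
all capillaries: its segment velocity is the cumulative entered
capillary volume flow over the main-vein cross-section, and its ω₂
relates the entered capillary J plus upstream main-vein J to the local
hemolymph mass flow. The total `ṅ_O₂ = (ΣJ_cap + ΣJ_mv)/M_O2`.

The explicit (lagged-sum) march is first-order accurate; with the
default segmentation a 10× refinement moves the total by <0.4%, and an
independent continuous ODE integration `dM/dx = g·(ω_max − ω₂(M))`
along each capillary agrees with the marched totals to ~0.01%.

### The headline total and its sensitivity

With all defaults the model returns ṅ_O₂ = 1.33·10⁻¹⁰ mol s⁻¹, inside
the measured band (1.04 ± 0.25)·10⁻¹⁰ mol s⁻¹ but about 21% above the
1.10·10⁻¹⁰ obtained when the velocity field comes from a full 3-D CFD
solution of the same geometry. The discrepancy is a property of the
velocity distribution, not of the transport law: the total is bounded
above by ρ·Q·ω_max/(1−X) (all printed constants) times a utilization
set by how evenly flow spreads over the capillaries — a perfectly
uniform distribution gives 1.48·10⁻¹⁰, the resistance-tree spread gives
1.33·10⁻¹⁰, and stronger spreads (as a CFD velocity field with junction
losses, or non-uniform capillary lengths, would produce) push the total
toward 1.1·10⁻¹⁰. Since capillary lengths and the CFD field are not
recoverable, the package reports the 1-D value and exposes the
geometry and flow inputs for sensitivity work
(`gen_perturbed_network`, `solve_network_flow`).

## Synthetic data

The generators emulate the study conditions, not arbitrary data:
traces default to the measured dormant rate 1.04·10⁻¹⁰ mol s⁻¹ at
25 °C, 20 ml chamber, 6 h duration, Gaussian sensor noise at half the
0.01 %O₂ resolution, relative humidity drawn from the observed 25–50%
band, and a linear casing-temperature drift; cohorts default to the
25 °C fit (α = 1.221, b = 2.835·10⁻¹³; 30 °C and 38 °C parameter sets
are shipped alongside) with shell-free masses uniform on 0.06–0.2 g and
multiplicative lognormal rate scatter (σ = 0.3, reproducing R² ≈ 0.9
fits at n = 25). They do **not** emulate activity phases, humidity
dependence of metabolism, O₂ bursts, or drifting chamber pressure —
passing recovery tests therefore demonstrates correctness of the
reduction chain, not robustness to every field artefact. All generators
are deterministic under a fixed seed.

## Degenerate inputs and tie-breaks

Zero humidity leaves pressure untouched; a vapour pressure exceeding
total pressure raises. A constant-O₂ trace returns rate 0; fewer than
10 samples raise; non-monotone traces are flagged via R², not raised.
Power-law fits require ≥3 distinct masses (all-equal masses raise a
singularity error). Isobole queries with no real roots return an empty
contour. ω₂ clamping takes effect only at saturation, where the
continuity solution itself sends J → 0. Perturbation jitter is capped
below lognormal σ = 0.5 to keep geometries physical.

## Problem sizes

Default runs march 37×40 + 240 segments and solve a 24-junction linear
tree — milliseconds on one core. The statistical calibrations in the
test suite use 200 synthetic cohorts (n = 25) for CI coverage and 100
seeded traces for rate-recovery coverage; the grid-refinement check
uses a 10× finer segmentation (400/2400 segments).
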