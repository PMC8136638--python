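"""Allometric scaling of metabolic rate and the temperature x mass
response surface.

The metabolic rate of *X. derbentina* follows the allometric law
``MR = b * m**alpha`` with a temperature-dependent exponent. Combining
the power fits at several temperatures yields a response surface that is
quadratic in both shell-free mass and temperature; its zero-level
isoboles mark the theoretical physiological limits (zero O2 consumption)
at low and high ambient temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SpecimenRecord",
    "PowerFit",
    "ResponseSurfaceCoeffs",
    "ShellModel",
    "DEFAULT_RESPONSE_SURFACE",
    "POWER_FIT_DEFAULTS",
    "fit_power_law",
    "shell_free_mass",
    "eval_response_surface",
    "zero_isobole_roots",
    "isoboles",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured specimen: masses, shell diameter and O2 rate."""

    total_mass: float        # kg
    shell_diameter: float    # m
    shell_free_mass: float   # kg
    temp: float              # degC
    o2_rate: float           # mol s-1

    def __post_init__(self) -> None:
        if not 0 < self.shell_free_mass <= self.total_mass:
            raise ValueError("need 0 < shell_free_mass <= total_mass")
        if self.o2_rate < 0:
            raise ValueError("o2_rate must be non-negative")


@dataclass(frozen=True)
class PowerFit:
    """Fitted allometric law MR = b * m**alpha with 95% CIs."""

    alpha: float
    b: float                       # mol s-1 kg^(-alpha)
    r_squared: float
    ci_alpha: tuple[float, float]
    ci_b: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def predict(self, mass):
        return self.b * np.asarray(mass, float) ** self.alpha


#: Fitted scaling-law parameters (alpha, b) for dormant X. derbentina
#: cohorts at the three test temperatures; used as generator defaults.
POWER_FIT_DEFAULTS = {
    25.0: (1.221, 2.835e-13),
    30.0: (1.033, 8.216e-13),
    38.0: (0.689, 2.18e-12),
}


def fit_power_law(
    records: Sequence[SpecimenRecord],
    method: str = "nls",
) -> PowerFit:
    """Fit MR = b * m**alpha to a cohort of specimens.

    Parameters
    ----------
    records : sequence of SpecimenRecord
        At least 3 specimens with positive shell-free masses and rates.
    method : {"nls", "loglog"}
        "nls" (default) fits on the original scale by nonlinear least
        squares; "loglog" uses the closed-form log-log OLS solution.
        R^2 is always computed on the original scale.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    m = np.array([r.shell_free_mass for r in records], float)
    mr = np.array([r.o2_rate for r in records], float)
    if np.any(m <= 0) or np.any(mr <= 0):
        raise ValueError("masses and rates must be positive")
    if np.ptp(m) == 0:
        raise ValueError("singular fit: all masses are equal")

    # closed-form log-log solution, also the NLS starting point
    ll = stats.linregress(np.log(m), np.log(mr))
    alpha0, b0 = ll.slope, np.exp(ll.intercept)

    n = len(records)
    if method == "loglog":
        alpha, b = alpha0, b0
        # delta-method covariance on (alpha, log b) from the OLS fit
        se_alpha = ll.stderr
        se_b = b * ll.intercept_stderr
        cov = np.diag([se_alpha**2, se_b**2])
    elif method == "nls":
        popt, cov = optimize.curve_fit(
            lambda x, a, bb: bb * x**a, m, mr, p0=(alpha0, b0), maxfev=10000
        )
        alpha, b = popt
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = mr - b * m**alpha
    ss_tot = float(np.sum((mr - mr.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    tval = stats.t.ppf(0.975, max(n - 2, 1))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return PowerFit(
        alpha=float(alpha),
        b=float(b),
        r_squared=min(r2, 1.0),
        ci_alpha=(float(alpha - tval * se[0]), float(alpha + tval * se[0])),
        ci_b=(float(b - tval * se[1]), float(b + tval * se[1])),
        n=n,
    )


@dataclass(frozen=True)
class ShellModel:
    """Cubic map from shell diameter to shell mass.

    shell_mass(d) = c0 + c1*d + c2*d**2 + c3*d**3, with d in m and the
    mass in kg. The default is a pure cubic chosen so that a 1 cm shell
    weighs about 0.09 g (a plausible shell fraction for this species);
    the true coefficients are a config input.
    """

    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 90.0   # kg m-3

    def shell_mass(self, diameter):
        d = np.asarray(diameter, float)
        mass = self.c0 + d * (self.c1 + d * (self.c2 + d * self.c3))
        return mass if mass.ndim else float(mass)


def shell_free_mass(total_mass, diameter, shell: ShellModel):
    """Subtract the modelled shell mass; negative results clip to 0 with a warning."""
    out = np.asarray(total_mass, float) - shell.shell_mass(diameter)
    if np.any(out < 0):
        warnings.warn(
            "shell model exceeds total mass for some specimens; clipping to 0",
            stacklevel=2,
        )
        out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ResponseSurfaceCoeffs:
    """Nine coefficients of the O2(m, T) response surface.

    O2(m, T) = A(m) + B(m)*T + C(m)*T**2 with A, B, C quadratic in m;
    returns mol s-1 for m in kg and T in degC.
    """

    a1: float
    a2: float
    a3: float
    b1: float
    b2: float
    b3: float
    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        vals = [getattr(self, f) for f in "a1 a2 a3 b1 b2 b3 c1 c2 c3".split()]
        if not all(np.isfinite(vals)):
            raise ValueError("all 9 coefficients must be finite")

    def t_polynomial(self, m):
        """Coefficients (A, B, C) of the quadratic in T at mass m."""
        m = np.asarray(m, float)
        a = self.a1 + m * (self.a2 + m * self.a3)
        b = self.b1 + m * (self.b2 + m * self.b3)
        c = self.c1 + m * (self.c2 + m * self.c3)
        return a, b, c


#: Response-surface coefficients fitted for X. derbentina (m in kg, T in
#: degC, rate in mol s-1). Masses are shell-free.
DEFAULT_RESPONSE_SURFACE = ResponseSurfaceCoeffs(
    a1=-1.1549e-11, a2=-5.9971e-6, a3=9.2619e-3,
    b1=-6.5462e-13, b2=4.6534e-7, b3=-4.9078e-4,
    c1=3.2832e-14, c2=-7.7807e-9, c3=6.2120e-6,
)

#: Shell-free mass range (kg) covered by the measured cohorts; surface
#: evaluations outside the measured (m, T) region are extrapolations.
MEASURED_MASS_RANGE = (6e-5, 2e-4)
MEASURED_TEMP_RANGE = (20.0, 38.0)


def eval_response_surface(
    m,
    temp,
    coeffs: ResponseSurfaceCoeffs = DEFAULT_RESPONSE_SURFACE,
    warn_extrapolation: bool = False,
):
    """Evaluate the response surface at mass m (kg) and temperature T (degC)."""
    m = np.asarray(m, float)
    t = np.asarray(temp, float)
    if warn_extrapolation:
        if (
            np.any(m < MEASURED_MASS_RANGE[0]) or np.any(m > MEASURED_MASS_RANGE[1])
            or np.any(t < MEASURED_TEMP_RANGE[0]) or np.any(t > MEASURED_TEMP_RANGE[1])
        ):
            warnings.warn("response surface evaluated outside the measured region", stacklevel=2)
    a, b, c = coeffs.t_polynomial(m)
    out = a + t * (b + t * c)
    return out if out.ndim else float(out)


def zero_isobole_roots(m, coeffs: ResponseSurfaceCoeffs = DEFAULT_RESPONSE_SURFACE,
                       level: float = 0.0):
    """Analytic temperature roots of O2(m, T) = level at fixed mass.

    Returns the pair (T_low, T_high) in degC, or ``None`` when no real
    roots exist (level above the surface maximum at that mass).
    """
    a, b, c = coeffs.t_polynomial(float(m))
    a = a - level
    if c == 0:
        if b == 0:
            return None
        root = -a / b
        return (root, root)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * c), (-b + sq) / (2 * c)))
    return (float(roots[0]), float(roots[1]))


def isoboles(
    coeffs: ResponseSurfaceCoeffs,
    levels: Sequence[float],
    m_grid,
):
    """Constant-consumption contours in the (mass, temperature) plane.

    Because the surface is quadratic in T at fixed m, every contour is
    obtained analytically from the quadratic formula; masses with no real
    roots contribute nothing to that contour.

    Returns
    -------
    dict
        level -> ndarray of shape (k, 3) with columns (m, T_low, T_high).
    """
    m_grid = np.asarray(m_grid, float)
    out = {}
    for level in levels:
        rows = []
        for m in m_grid:
            roots = zero_isobole_roots(m, coeffs, level=level)
            if roots is not None:
                rows.append((m, roots[0], roots[1]))
        out[level] = np.array(rows).reshape(-1, 3)
    return out
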