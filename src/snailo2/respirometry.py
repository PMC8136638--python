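"""Closed-chamber respirometry reduction.

A sealed chamber of known volume holds one snail; an electrochemical
sensor records the O2 volume percentage together with total pressure,
temperature and relative humidity. The O2 reading is first corrected for
the sensor's temperature drift (fitted on empty-chamber baselines), the
water-vapour partial pressure is removed from the total pressure, the
ideal-gas law converts the dry O2 fraction into moles of O2, and the
consumption rate is the (negative) least-squares slope of the mole time
series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_GAS, kelvin

__all__ = [
    "RespirometryTrace",
    "DriftModel",
    "RateEstimate",
    "saturated_vapor_pressure",
    "dry_pressure",
    "moles_oxygen",
    "fit_drift",
    "drift_correct",
    "consumption_rate",
    "read_trace_csv",
    "write_trace_csv",
]

#: Validity range of the Magnus coefficients, degC.
MAGNUS_RANGE = (-45.0, 60.0)

#: Resolution of the O2 sensor, %O2.
SENSOR_RESOLUTION = 0.01


def saturated_vapor_pressure(temp_c):
    """Saturated water vapour pressure by the Magnus approximation.

    Parameters
    ----------
    temp_c : float or array_like
        Temperature in degC; must lie in the Magnus validity range
        (-45, 60) degC.

    Returns
    -------
    float or ndarray
        Saturation pressure in Pa (611.2 Pa at 0 degC).
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= MAGNUS_RANGE[0]) or np.any(t >= MAGNUS_RANGE[1]):
        raise ValueError(
            f"temperature outside Magnus validity range {MAGNUS_RANGE} degC"
        )
    e_hpa = 6.112 * np.exp(17.62 * t / (243.12 + t))
    return e_hpa * 100.0 if t.ndim else float(e_hpa * 100.0)


def dry_pressure(p_total, rel_humidity, temp_c):
    """Total pressure minus the water-vapour partial pressure, Pa.

    The vapour pressure is ``rel_humidity * saturated_vapor_pressure``.
    Raises ``ValueError`` if the result would be negative (inconsistent
    inputs).
    """
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any(rh < 0) or np.any(rh > 1):
        raise ValueError("relative humidity must be a fraction in [0, 1]")
    p = np.asarray(p_total, dtype=float) - rh * saturated_vapor_pressure(temp_c)
    if np.any(p < 0):
        raise ValueError("dry pressure is negative: inconsistent inputs")
    return p if p.ndim else float(p)


def moles_oxygen(p_dry, r_o2, volume, temp_c):
    """Moles of O2 in the chamber from Dalton's law and the ideal-gas law.

    ``n = r_o2 * p_dry * V / (R * T)``, exactly linear in ``p_dry``,
    ``r_o2`` and ``volume``.
    """
    r = np.asarray(r_o2, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("r_o2 must be a fraction in [0, 1]")
    n = r * np.asarray(p_dry, float) * volume / (R_GAS * kelvin(np.asarray(temp_c, float)))
    return n if n.ndim else float(n)


@dataclass
class RespirometryTrace:
    """Time series of chamber state during one respirometry run.

    ``temp`` is the (water-bath conditioned) chamber temperature used in
    the gas accounting; ``casing_temp`` is the temperature at the sensor
    casing, the quantity the drift model is fitted on. When the casing
    record is absent it defaults to the chamber temperature. Scalar
    values are broadcast to the length of ``t``.
    """

    t: np.ndarray                 # s, strictly increasing
    o2_percent: np.ndarray        # sensor reading, % O2
    p_total: np.ndarray           # Pa
    temp: np.ndarray              # degC, chamber
    rel_humidity: np.ndarray      # fraction 0-1
    chamber_volume: float         # m3
    casing_temp: np.ndarray | None = None  # degC, sensor casing

    def __post_init__(self) -> None:
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        n = self.t.size
        if self.casing_temp is None:
            self.casing_temp = self.temp
        for name in ("o2_percent", "p_total", "temp", "rel_humidity", "casing_temp"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), float), (n,)).copy()
            setattr(self, name, arr)
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.o2_percent < 0) or np.any(self.o2_percent > 100):
            raise ValueError("o2_percent outside [0, 100]")
        if np.any(self.rel_humidity < 0) or np.any(self.rel_humidity > 1):
            raise ValueError("rel_humidity outside [0, 1]")
        if self.chamber_volume <= 0:
            raise ValueError("chamber_volume must be positive")

    def moles_o2(self) -> np.ndarray:
        """Mole time series n_O2(t) from the current O2 reading."""
        p_dry = dry_pressure(self.p_total, self.rel_humidity, self.temp)
        return moles_oxygen(p_dry, self.o2_percent / 100.0, self.chamber_volume, self.temp)


@dataclass(frozen=True)
class DriftModel:
    """Linear dependence of the O2 reading on sensor-casing temperature."""

    slope: float                  # %O2 per degC
    reference_temp: float         # degC
    correlation: float = 0.0      # Pearson r of the baseline fit

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def fit_drift(baseline: RespirometryTrace) -> DriftModel:
    """Fit the casing-temperature drift on an empty-chamber baseline trace."""
    if np.ptp(baseline.casing_temp) == 0:
        raise ValueError("baseline casing temperature is constant; drift is unidentifiable")
    res = stats.linregress(baseline.casing_temp, baseline.o2_percent)
    return DriftModel(
        slope=float(res.slope),
        reference_temp=float(np.mean(baseline.casing_temp)),
        correlation=float(res.rvalue),
    )


def drift_correct(trace: RespirometryTrace, drift: DriftModel) -> RespirometryTrace:
    """Remove the fitted casing-temperature drift from the O2 signal.

    Applied to the baseline trace itself the corrected signal is constant
    to within the 0.01 %O2 sensor resolution.
    """
    corrected = trace.o2_percent - drift.slope * (trace.casing_temp - drift.reference_temp)
    return dataclasses.replace(trace, o2_percent=corrected)


@dataclass(frozen=True)
class RateEstimate:
    """O2 consumption rate with its OLS standard error and fit quality."""

    rate: float          # mol s-1, positive for consumption
    stderr: float        # mol s-1
    r_squared: float
    n_samples: int

    @property
    def low_quality(self) -> bool:
        """Flag for pathological (non-monotone, noisy) traces."""
        return self.r_squared < 0.5


def consumption_rate(trace: RespirometryTrace) -> RateEstimate:
    """O2 consumption rate as the negative OLS slope of n_O2(t).

    The trace should be drift-corrected and hold at least 10 samples. A
    poor linear fit does not raise; it is reported through ``r_squared``
    (and the ``low_quality`` flag).
    """
    if trace.t.size < 10:
        raise ValueError("need at least 10 samples to estimate a rate")
    n_o2 = trace.moles_o2()
    res = stats.linregress(trace.t, n_o2)
    return RateEstimate(
        rate=float(-res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_samples=trace.t.size,
    )


_CSV_COLUMNS = ["t_s", "o2_percent", "p_total_pa", "temp_c", "rh_frac"]


def read_trace_csv(path, chamber_volume: float) -> RespirometryTrace:
    """Read a trace from CSV (columns t_s, o2_percent, p_total_pa, temp_c, rh_frac)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    casing = df["casing_temp_c"].to_numpy() if "casing_temp_c" in df.columns else None
    return RespirometryTrace(
        t=df["t_s"].to_numpy(),
        o2_percent=df["o2_percent"].to_numpy(),
        p_total=df["p_total_pa"].to_numpy(),
        temp=df["temp_c"].to_numpy(),
        rel_humidity=df["rh_frac"].to_numpy(),
        chamber_volume=chamber_volume,
        casing_temp=casing,
    )


def write_trace_csv(trace: RespirometryTrace, path) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "o2_percent": trace.o2_percent,
            "p_total_pa": trace.p_total,
            "temp_c": trace.temp,
            "rh_frac": trace.rel_humidity,
            "casing_temp_c": trace.casing_temp,
        }
    ).to_csv(path, index=False)
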