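"""Gas-exchange energetics: metabolic power, gross efficiency, V̇O₂max, time above thresholds.

Metabolic power input follows the linear RER-dependent energetic equivalent of
oxygen, PI = V̇O₂[L·s⁻¹] · (4840·RER + 16890) J·L⁻¹, with RER clamped at 1.0
because the equivalent is undefined for net anaerobic gas exchange.  Gross
efficiency is mechanical power output as a percentage of PI.  V̇O₂max is the
best 60-s rolling mean of the sampled series; session metrics (time at or
above a fraction of V̇O₂max/HRmax, aerobic energy turnover) are evaluated over
work-interval samples only, duration-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GasSeries",
    "EnergeticsResult",
    "InsufficientDataError",
    "metabolic_power",
    "gross_efficiency",
    "vo2max_from_series",
    "po_vo2max",
    "time_at_or_above",
    "aerobic_energy",
    "WORK_PREFIX",
]

O2_EQUIV_SLOPE = 4840.0   # J per L O2 per unit RER
O2_EQUIV_INTERCEPT = 16890.0  # J per L O2

WORK_PREFIX = "work"  # segment labels like "work-3" mark work intervals


class InsufficientDataError(ValueError):
    """Series too short for the requested window/summary."""


@dataclass
class GasSeries:
    """Uniformly sampled V̇O₂/RER/HR/power trace for one test or session.

    vo2 is absolute (mL·min⁻¹); segment labels distinguish warm-up, work
    intervals ("work-<k>") and recoveries.  Missing gas channels are NaN.
    """

    sample_period: float              # s (5 for tests, 10 for sessions)
    power: np.ndarray                 # W
    vo2: np.ndarray                   # mL/min
    rer: np.ndarray
    hr: np.ndarray                    # bpm
    segments: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        self.power = np.asarray(self.power, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.rer = np.asarray(self.rer, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.segments is None:
            self.segments = np.full(self.power.shape, "all", dtype=object)
        else:
            self.segments = np.asarray(self.segments, dtype=object)
        n = self.power.size
        for name in ("vo2", "rer", "hr", "segments"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length != power length {n}")
        if np.nanmin(self.vo2, initial=0.0) < 0:
            raise ValueError("vo2 must be non-negative")

    @property
    def n(self) -> int:
        return int(self.power.size)

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n * self.sample_period

    def work_mask(self) -> np.ndarray:
        return np.array([str(s).startswith(WORK_PREFIX) for s in self.segments])


@dataclass(frozen=True)
class EnergeticsResult:
    """Aerobic energetics over a set of work intervals."""

    pi: float            # metabolic power input, J/s
    ge: float            # gross efficiency, %
    energy_rate: float   # kJ/s
    energy_total: float  # kJ


def metabolic_power(vo2_l_s, rer):
    """Metabolic power input PI (J·s⁻¹) from V̇O₂ in L·s⁻¹ and RER.

    PI = V̇O₂ · (4840·RER + 16890).  RER above 1.0 is clamped to 1.0 (the
    energetic equivalent of O₂ is only defined up to full carbohydrate
    oxidation); RER outside [0.6, 1.3] is rejected as non-physiological.
    Accepts scalars or arrays.
    """
    vo2 = np.asarray(vo2_l_s, dtype=float)
    r = np.asarray(rer, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be non-negative")
    finite = np.isfinite(r)
    if np.any((r[finite] < 0.6) | (r[finite] > 1.3)):
        raise ValueError("RER outside physiological range [0.6, 1.3]")
    rer_eff = np.minimum(r, 1.0)
    out = vo2 * (O2_EQUIV_SLOPE * rer_eff + O2_EQUIV_INTERCEPT)
    return float(out) if out.ndim == 0 else out


def gross_efficiency(power: float, pi: float) -> float:
    """Gross efficiency (%) = 100 · mechanical power / metabolic power input."""
    if pi <= 0:
        raise ValueError("metabolic power input must be positive")
    if power < 0:
        raise ValueError("power must be non-negative")
    return 100.0 * power / pi


def _best_rolling_mean(x: np.ndarray, window: int) -> float:
    # cumulative-sum rolling mean; O(n)
    c = np.concatenate([[0.0], np.cumsum(x)])
    sums = c[window:] - c[:-window]
    return float(sums.max() / window)


def vo2max_from_series(series: GasSeries, window_s: float = 60.0) -> float:
    """V̇O₂max (mL·min⁻¹): best rolling mean over a 60-s window.

    With 5-s sampling this is the mean of the 12 highest consecutive
    measurements; the window is defined in seconds so 10-s sampling uses 6
    samples.
    """
    window = int(round(window_s / series.sample_period))
    if series.n < window:
        raise InsufficientDataError(
            f"need >= {window} samples ({window_s:g} s at {series.sample_period:g}-s period), got {series.n}"
        )
    return _best_rolling_mean(series.vo2, window)


def po_vo2max(power: np.ndarray, sample_period: float, window_s: float = 60.0) -> float:
    """Mean power (W) over the final 60 s of an incremental test trace."""
    power = np.asarray(power, dtype=float)
    window = int(round(window_s / sample_period))
    if power.size < window:
        raise InsufficientDataError(f"trace shorter than {window_s:g} s")
    return float(power[-window:].mean())


def time_at_or_above(
    series: GasSeries,
    reference: float,
    fraction: float = 0.9,
    channel: str = "vo2",
) -> float:
    """Seconds of work-interval time with ``channel`` ≥ fraction·reference.

    Only work-interval samples count; recoveries between intervals are
    excluded.  A series with no labeled work intervals returns 0 s with a
    warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if reference <= 0:
        raise ValueError("reference must be positive")
    mask = series.work_mask()
    if not mask.any():
        warnings.warn("series has no work-interval segments; returning 0 s", stacklevel=2)
        return 0.0
    values = getattr(series, channel)[mask]
    return float(np.count_nonzero(values >= fraction * reference) * series.sample_period)


def aerobic_energy(
    series: GasSeries,
    body_mass: Optional[float] = None,
    vo2_relative: bool = False,
) -> EnergeticsResult:
    """Aerobic energy turnover over work intervals.

    The energy rate (kJ·s⁻¹) comes from the duration-weighted mean V̇O₂ and
    RER across all work-interval samples; the total is rate × accumulated
    work-interval duration.  If the series stores relative V̇O₂
    (mL·min⁻¹·kg⁻¹), ``body_mass`` converts to absolute.
    """
    mask = series.work_mask()
    if not mask.any():
        raise InsufficientDataError("series has no work-interval segments")
    vo2 = series.vo2[mask]
    rer = series.rer[mask]
    if np.isnan(rer).any():
        raise ValueError("RER missing over work intervals; no default is substituted")
    if vo2_relative:
        if body_mass is None or body_mass <= 0:
            raise ValueError("body_mass required to resolve relative vo2")
        vo2 = vo2 * body_mass
    # samples are uniform, so the duration-weighted mean is the plain mean
    mean_vo2_l_s = float(vo2.mean()) / 60000.0  # mL/min -> L/s
    mean_rer = float(rer.mean())
    pi = metabolic_power(mean_vo2_l_s, mean_rer)
    duration = float(mask.sum()) * series.sample_period
    power = series.power[mask]
    ge = gross_efficiency(float(power.mean()), pi) if pi > 0 else 0.0
    rate = pi / 1000.0
    return EnergeticsResult(pi=pi, ge=ge, energy_rate=rate, energy_total=rate * duration)
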