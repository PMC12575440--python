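"""Training-load quantification: 5-zone classification, TRIMP, session and week summaries.

Endurance intensity is binned into five zones relative to the mean power (or
heart rate) of a 40-min maximal trial.  The printed zone ranges
(<55, 56–75, 76–90, 91–105, >106 %) contain rounding gaps; contiguous
half-open bins [0,55), [55,75), [75,90), [90,105), [105,∞) are used so every
minute lands in exactly one zone.  TRIMP weights each minute by its zone
number (1 min in zone z = z TRIMP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gasex import GasSeries, time_at_or_above

__all__ = [
    "ZoneScheme",
    "WeekSummary",
    "SessionSummary",
    "classify_zone",
    "trimp",
    "summarize_session",
    "summarize_week",
]

ZONE_BOUNDARIES = (55.0, 75.0, 90.0, 105.0)


@dataclass(frozen=True)
class ZoneScheme:
    """Five-zone intensity scheme anchored to a 40-min maximal-trial reference.

    basis: 'percent_po_40min' (power, default) or 'percent_hr_40min'.
    """

    basis: str = "percent_po_40min"
    boundaries: tuple[float, float, float, float] = ZONE_BOUNDARIES
    reference: Optional[float] = None  # W or bpm; None when intensities are already %

    def __post_init__(self) -> None:
        if self.basis not in ("percent_po_40min", "percent_hr_40min"):
            raise ValueError(f"unknown zone basis {self.basis!r}")
        if list(self.boundaries) != sorted(self.boundaries) or len(set(self.boundaries)) != 4:
            raise ValueError("boundaries must be four strictly increasing cut points")
        if self.reference is not None and self.reference <= 0:
            raise ValueError("reference must be positive")


def classify_zone(intensity_pct, scheme: ZoneScheme = ZoneScheme()):
    """Zone 1–5 for an intensity in % of the 40-min reference.

    Boundary values go to the upper zone (90.0% → zone 4).  Vectorized.
    """
    x = np.asarray(intensity_pct, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity must be non-negative")
    z = np.searchsorted(np.asarray(scheme.boundaries), x, side="right") + 1
    return int(z) if z.ndim == 0 else z


def trimp(durations_min: Sequence[float]) -> float:
    """Training impulse: Σ duration(zone z, minutes) · z over the 5 zones."""
    d = np.asarray(durations_min, dtype=float)
    if d.size != 5:
        raise ValueError("expected 5 per-zone durations")
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    return float(np.dot(d, np.arange(1, 6)))


@dataclass
class SessionSummary:
    """Duration-weighted work-interval means for one interval session (Table-1 shape)."""

    participant_id: str
    hr_mean: float                # bpm
    pct_hr_max: float             # %
    po_w_kg: float                # W/kg
    pct_po_vo2max: float          # %
    pct_vo2max: float             # % (NaN when gas not measured)
    time_ge90_vo2max_s: float
    time_ge90_hrmax_s: float
    energy_rate_kj_s: float
    energy_total_kj: float
    rpe_mean: float
    srpe: float


def summarize_session(
    series: GasSeries,
    *,
    participant_id: str = "",
    vo2max: float,
    hr_max: float,
    po_vo2max_ref: float,
    body_mass: float,
    rpe_per_interval: Optional[Sequence[float]] = None,
    srpe: float = float("nan"),
) -> SessionSummary:
    """Summarize one interval session against the participant's reference maxima.

    All means are duration-weighted over work-interval samples; time above
    90% of V̇O₂max/HRmax uses the same work-interval restriction.
    """
    for name, v in (("vo2max", vo2max), ("hr_max", hr_max),
                    ("po_vo2max_ref", po_vo2max_ref), ("body_mass", body_mass)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"reference {name} must be positive and finite")
    mask = series.work_mask()
    if not mask.any():
        raise ValueError("session has no labeled work intervals")
    po = float(series.power[mask].mean())
    hr = float(np.nanmean(series.hr[mask]))
    gas_present = np.isfinite(series.vo2[mask]).any()
    if gas_present:
        vo2 = float(np.nanmean(series.vo2[mask]))
        pct_vo2max = 100.0 * vo2 / vo2max
        t90_vo2 = time_at_or_above(series, vo2max, 0.9, channel="vo2")
        from .gasex import aerobic_energy

        energetics = aerobic_energy(series)
        rate, total = energetics.energy_rate, energetics.energy_total
    else:
        pct_vo2max = float("nan")
        t90_vo2 = float("nan")
        rate = total = float("nan")
    t90_hr = time_at_or_above(series, hr_max, 0.9, channel="hr")
    rpe = float(np.mean(rpe_per_interval)) if rpe_per_interval is not None else float("nan")
    return SessionSummary(
        participant_id=participant_id,
        hr_mean=hr,
        pct_hr_max=100.0 * hr / hr_max,
        po_w_kg=po / body_mass,
        pct_po_vo2max=100.0 * po / po_vo2max_ref,
        pct_vo2max=pct_vo2max,
        time_ge90_vo2max_s=t90_vo2,
        time_ge90_hrmax_s=t90_hr,
        energy_rate_kj_s=rate,
        energy_total_kj=total,
        rpe_mean=rpe,
        srpe=float(srpe),
    )


@dataclass
class WeekSummary:
    """Per-zone endurance durations, TRIMP and activity totals for one log window."""

    zone_min: np.ndarray = field(default_factory=lambda: np.zeros(5))
    trimp: float = 0.0
    strength_min: float = 0.0
    core_min: float = 0.0
    total_min: float = 0.0
    feeling_legs: float = float("nan")
    n_rejected: int = 0


def summarize_week(log: pd.DataFrame, scheme: ZoneScheme = ZoneScheme()) -> WeekSummary:
    """Aggregate a training log into per-zone durations, TRIMP and totals.

    Expected columns: activity ('endurance'/'strength'/'core'),
    zone_or_percent (zone 1–5 or intensity %), duration_min; optional
    feeling_legs.  Endurance rows with neither a valid zone nor an intensity
    are rejected and counted, not silently dropped.
    """
    zones = np.zeros(5)
    strength = core = 0.0
    rejected = 0
    if log.empty:
        return WeekSummary()
    for _, row in log.iterrows():
        dur = float(row.get("duration_min", np.nan))
        if not np.isfinite(dur) or dur < 0:
            rejected += 1
            continue
        act = str(row.get("activity", "endurance")).lower()
        if act == "strength":
            strength += dur
        elif act == "core":
            core += dur
        else:
            zp = row.get("zone_or_percent", np.nan)
            try:
                zp = float(zp)
            except (TypeError, ValueError):
                rejected += 1
                continue
            if not np.isfinite(zp):
                rejected += 1
                continue
            if zp in (1.0, 2.0, 3.0, 4.0, 5.0):
                z = int(zp)
            else:
                z = classify_zone(zp, scheme)
            zones[z - 1] += dur
    feeling = float("nan")
    if "feeling_legs" in log.columns:
        vals = pd.to_numeric(log["feeling_legs"], errors="coerce").dropna()
        if len(vals):
            feeling = float(vals.mean())
    return WeekSummary(
        zone_min=zones,
        trimp=trimp(zones),
        strength_min=strength,
        core_min=core,
        total_min=float(zones.sum() + strength + core),
        feeling_legs=feeling,
        n_rejected=rejected,
    )
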