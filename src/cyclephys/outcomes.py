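"""Performance battery assembly and the composite endurance performance index.

The prolonged test battery runs, in a fixed order: lactate profile → 10-s
sprint → incremental V̇O₂max test → 30-min bout at the 2-mmol·L⁻¹ power plus
repeated profile steps (semi-fatigued efficiency) → 15-min maximal trial.
This module computes the trial-level outcomes and the endurance performance
index: the mean, over PO_V̇O₂max, PO_4mmol and PO_15min, of each indicator
normalized by its maximum over the reference set of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .gasex import GasSeries, InsufficientDataError, _best_rolling_mean

__all__ = [
    "BatteryResult",
    "IndexBasis",
    "InvalidTrialError",
    "INDEX_INDICATORS",
    "po_15min",
    "po_10sec",
    "assemble_battery",
    "frac_util_15min",
    "endurance_index",
]

INDEX_INDICATORS = ("po_vo2max", "po_4mmol", "po_15min")


class InvalidTrialError(ValueError):
    """Trial trace does not satisfy the protocol (e.g. too short)."""


@dataclass
class BatteryResult:
    """One participant × block × timepoint bundle of battery outcomes.

    Powers are body-mass normalized (W·kg⁻¹), V̇O₂max relative
    (mL·min⁻¹·kg⁻¹), fractional utilizations and gross efficiencies in %.
    """

    participant_id: str
    block: str
    timepoint: str
    body_mass: float
    po_4mmol: float
    po_vo2max: float
    po_15min: float
    po_10sec: float
    vo2max_rel: float
    frac_util_4mmol: float
    frac_util_15min: float
    ge_fresh_3rd: float
    ge_fresh_2nd: float
    ge_tired_3rd: float
    ge_tired_2nd: float

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def po_15min(power: np.ndarray, sample_period: float, body_mass: float) -> float:
    """Mean power of the 15-min maximal trial, in W·kg⁻¹.

    The trace must cover at least 95% of the nominal 900 s.
    """
    power = np.asarray(power, dtype=float)
    duration = power.size * sample_period
    if duration < 0.95 * 900.0:
        raise InvalidTrialError(f"trial covers {duration:g} s < 95% of 900 s")
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return float(power.mean()) / body_mass


def po_10sec(power: np.ndarray, sample_period: float, body_mass: float) -> float:
    """Best 10-s rolling mean power of the sprint, in W·kg⁻¹."""
    power = np.asarray(power, dtype=float)
    window = int(round(10.0 / sample_period))
    if window < 1 or power.size < window:
        raise InsufficientDataError("sprint trace shorter than 10 s")
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return _best_rolling_mean(power, window) / body_mass


def frac_util_15min(series: GasSeries, vo2max: float) -> float:
    """Fractional utilization (% of V̇O₂max) over the 15-min trial."""
    if vo2max <= 0:
        raise ValueError("vo2max must be positive")
    if series.n == 0:
        raise InsufficientDataError("empty series")
    return 100.0 * float(np.nanmean(series.vo2)) / vo2max


@dataclass(frozen=True)
class IndexBasis:
    """Per-indicator maxima over the reference set of observations.

    The reference set defaults to every observation entering the analysis
    (both blocks, both timepoints); storing the basis with results makes any
    alternative reference choice reproducible.
    """

    maxima: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [k for k in INDEX_INDICATORS if k not in self.maxima]
        if missing:
            raise ValueError(f"basis missing indicators: {missing}")
        if any(self.maxima[k] <= 0 for k in INDEX_INDICATORS):
            raise ValueError("indicator maxima must be positive")

    @classmethod
    def from_observations(cls, df: pd.DataFrame) -> "IndexBasis":
        return cls({k: float(df[k].max()) for k in INDEX_INDICATORS})


def assemble_battery(
    *,
    participant_id: str,
    block: str,
    timepoint: str,
    body_mass: float,
    profile,
    tired_steps,
    sprint_power: np.ndarray,
    sprint_period: float,
    vo2max_series: GasSeries,
    time_trial: GasSeries,
) -> BatteryResult:
    """Compute one BatteryResult from the raw trials of a prolonged battery.

    Follows the test order of the protocol: lactate profile → sprint →
    incremental V̇O₂max test → semi-fatigued repeated steps → 15-min trial.
    Gross efficiency is evaluated at the 3rd- and 2nd-last profile steps in
    the fresh state and at their semi-fatigued repetitions.
    """
    from .gasex import gross_efficiency, metabolic_power, po_vo2max as _po_vo2max
    from .gasex import vo2max_from_series
    from .lactate import fractional_utilization_at_power, po_at_lactate

    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    vo2max = vo2max_from_series(vo2max_series)
    po_vm = _po_vo2max(vo2max_series.power, vo2max_series.sample_period)
    po4_w = po_at_lactate(profile, 4.0)
    frac4 = fractional_utilization_at_power(profile, vo2max, po4_w)

    def _ge(step) -> float:
        pi = metabolic_power(step.vo2 / 60000.0, step.rer)
        return gross_efficiency(step.power, pi)

    fresh = profile.steps[-3:-1]
    if len(fresh) < 2 or len(tired_steps) < 2:
        raise ValueError("need the 3rd- and 2nd-last profile steps fresh and repeated")
    return BatteryResult(
        participant_id=participant_id,
        block=block,
        timepoint=timepoint,
        body_mass=body_mass,
        po_4mmol=po4_w / body_mass,
        po_vo2max=po_vm / body_mass,
        po_15min=po_15min(time_trial.power, time_trial.sample_period, body_mass),
        po_10sec=po_10sec(sprint_power, sprint_period, body_mass),
        vo2max_rel=vo2max / body_mass,
        frac_util_4mmol=frac4,
        frac_util_15min=frac_util_15min(time_trial, vo2max),
        ge_fresh_3rd=_ge(fresh[0]),
        ge_fresh_2nd=_ge(fresh[1]),
        ge_tired_3rd=_ge(tired_steps[0]),
        ge_tired_2nd=_ge(tired_steps[1]),
    )


def endurance_index(values: Mapping[str, float] | BatteryResult, basis: IndexBasis) -> float:
    """Composite endurance performance index in (0, 1].

    Mean over the three indicators of x_i / max(x), where max(x) is the
    basis maximum for that indicator.  All three indicators must be present.
    """
    if isinstance(values, BatteryResult):
        values = values.to_row()
    vals = []
    for k in INDEX_INDICATORS:
        v = values.get(k)
        if v is None or not np.isfinite(v):
            raise ValueError(f"indicator {k!r} missing; no partial index is computed")
        vals.append(v / basis.maxima[k])
    return float(np.mean(vals))
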