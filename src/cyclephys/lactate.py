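"""Incremental blood-lactate profile: step protocol and threshold interpolation.

The profile test starts at a fixed power (125 W, or 175 W for riders who
self-estimate their lactate threshold above 325 W) and climbs in 50-W steps of
5.5 min until blood lactate reaches 2 mmol·L⁻¹, then in 25-W steps until
4 mmol·L⁻¹.  Capillary lactate is sampled 30 s before the end of each step and
steady-state V̇O₂/RER are averaged over minutes 2.5–5.0.

Thresholds (power at a given lactate level, fractional utilization of V̇O₂max
at a given power) are obtained by piecewise-linear interpolation between the
two bracketing steps — never by a global fit, and never by extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StepProtocolSpec",
    "LactateStep",
    "LactateProfile",
    "NotBracketedError",
    "next_step_power",
    "po_at_lactate",
    "fractional_utilization_at_power",
]


class NotBracketedError(ValueError):
    """The requested level/power lies outside the range covered by the steps."""


@dataclass(frozen=True)
class StepProtocolSpec:
    """Incremental step protocol parameters (powers in W, durations in s)."""

    start_power: float = 125.0
    coarse_increment: float = 50.0
    fine_increment: float = 25.0
    step_duration: float = 330.0
    coarse_to_fine_lactate: float = 2.0  # mmol/L: switch to fine increments
    termination_lactate: float = 4.0     # mmol/L: stop the test

    def __post_init__(self) -> None:
        if self.coarse_increment <= 0 or self.fine_increment <= 0:
            raise ValueError("increments must be positive")
        if self.coarse_to_fine_lactate >= self.termination_lactate:
            raise ValueError("coarse-to-fine lactate must be below termination lactate")


#: Default protocol for riders with self-estimated lactate threshold > 325 W.
HIGH_START_POWER = 175.0


@dataclass(frozen=True)
class LactateStep:
    """One completed step: end-step lactate plus steady-state gas exchange."""

    power: float          # W
    lactate: float        # mmol/L, sampled 30 s before step end
    vo2: float = float("nan")   # mL/min, mean of minutes 2.5-5.0
    rer: float = float("nan")
    hr: float = float("nan")    # bpm

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError(f"step power must be positive, got {self.power}")
        if self.lactate < 0:
            raise ValueError(f"lactate must be non-negative, got {self.lactate}")
        if np.isfinite(self.rer) and not 0.6 <= self.rer <= 1.3:
            raise ValueError(f"RER {self.rer} outside physiological range [0.6, 1.3]")


@dataclass
class LactateProfile:
    """Ordered step records for one participant's incremental profile test.

    ``terminated`` is True when the final step reached the termination lactate
    (≥ 4 mmol·L⁻¹); a flat curve that never gets there is flagged False and
    cannot yield a 4-mmol threshold.
    """

    participant_id: str
    steps: list[LactateStep] = field(default_factory=list)
    terminated: bool = True

    def __post_init__(self) -> None:
        powers = [s.power for s in self.steps]
        if any(b <= a for a, b in zip(powers, powers[1:])):
            raise ValueError("step powers must be strictly increasing")

    @property
    def powers(self) -> np.ndarray:
        return np.array([s.power for s in self.steps], dtype=float)

    @property
    def lactates(self) -> np.ndarray:
        return np.array([s.lactate for s in self.steps], dtype=float)

    @property
    def vo2s(self) -> np.ndarray:
        return np.array([s.vo2 for s in self.steps], dtype=float)


def next_step_power(
    profile: LactateProfile | Sequence[LactateStep],
    spec: StepProtocolSpec = StepProtocolSpec(),
) -> Optional[float]:
    """Power of the next step under the protocol rules, or None to stop.

    Coarse (+50 W) while every lactate so far is below 2 mmol·L⁻¹, fine
    (+25 W) once any reading has reached 2, stop once any reading has reached
    the 4-mmol·L⁻¹ termination level.
    """
    steps = profile.steps if isinstance(profile, LactateProfile) else list(profile)
    if not steps:
        return spec.start_power
    powers = [s.power for s in steps]
    if any(b <= a for a, b in zip(powers, powers[1:])):
        raise ValueError("invalid state: step powers are not strictly increasing")
    lactates = [s.lactate for s in steps]
    if max(lactates) >= spec.termination_lactate:
        return None
    if max(lactates) >= spec.coarse_to_fine_lactate:
        return powers[-1] + spec.fine_increment
    return powers[-1] + spec.coarse_increment


def po_at_lactate(profile: LactateProfile, level: float) -> float:
    """Power output at a blood-lactate level, by bracketing-pair interpolation.

    If a step hits ``level`` exactly the first such step's power is returned
    (conservative under zero-slope segments).  Otherwise the first step at or
    above the level and its predecessor define the interpolation segment:

        P = P_lo + (level - La_lo) * (P_hi - P_lo) / (La_hi - La_lo)

    Raises NotBracketedError when the level is never reached, or lies below
    the first step's lactate (no extrapolation in either direction).
    """
    steps = profile.steps
    if not steps:
        raise NotBracketedError("empty profile")
    for i, s in enumerate(steps):
        if s.lactate == level:
            return s.power
        if s.lactate > level:
            if i == 0:
                raise NotBracketedError(
                    f"level {level} mmol/L below first step lactate {s.lactate}"
                )
            lo, hi = steps[i - 1], s
            frac = (level - lo.lactate) / (hi.lactate - lo.lactate)
            return lo.power + frac * (hi.power - lo.power)
    raise NotBracketedError(f"level {level} mmol/L never reached (max {max(s.lactate for s in steps)})")


def fractional_utilization_at_power(
    profile: LactateProfile, vo2max: float, power: float
) -> float:
    """%V̇O₂max at a query power, interpolating per-step %V̇O₂max vs power.

    Each step contributes 100·vo2/vo2max; the piecewise-linear curve of
    %V̇O₂max against step power is evaluated at ``power``.  The query must be
    bracketed by the step powers.
    """
    if vo2max <= 0:
        raise ValueError("vo2max must be positive")
    powers = profile.powers
    vo2s = profile.vo2s
    ok = np.isfinite(vo2s)
    powers, vo2s = powers[ok], vo2s[ok]
    if powers.size < 1:
        raise NotBracketedError("profile has no V̇O₂ measurements")
    if not (powers[0] <= power <= powers[-1]):
        raise NotBracketedError(
            f"power {power} W outside measured step range [{powers[0]}, {powers[-1]}] W"
        )
    pct = 100.0 * vo2s / vo2max
    return float(np.interp(power, powers, pct))
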