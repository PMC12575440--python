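"""Synthetic cyclist cohorts with known ground truth for every pipeline stage.

A latent physiological state per rider (V̇O₂max, gross efficiency, an
exponential-plus-baseline lactate–power curve, first-order V̇O₂ kinetics,
linear HR response) generates all raw inputs the analysis stages read:
incremental step tests, interval-session gas/power/HR time series, sprint and
time-trial traces, and training logs.  Block effects are drawn per rider as
percent changes (/-point changes for gross efficiency) around configurable
means, so recovery of the configured truth by the full pipeline is testable.

Defaults emulate the study cohort: n = 22 well-trained cyclists
(V̇O₂max 69.5 (6.0) mL·min⁻¹·kg⁻¹, body mass 70.8 (7.9) kg), a
moderate-intensity block (MIT: 5–7 × 10–14-min continuous intervals, RPE
14–15) and a high-intensity block (HIT: 5 × 8.75 min of 30/15-s intervals at
~118/60% of 40-min power, RPE 16–18).

All randomness flows through numpy SeedSequence sub-streams keyed by
(seed, purpose, participant), so the same seed reproduces every value
bit-for-bit and adding riders never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .gasex import GasSeries, metabolic_power
from .lactate import (
    HIGH_START_POWER,
    LactateProfile,
    LactateStep,
    StepProtocolSpec,
    next_step_power,
)

__all__ = [
    "Participant",
    "TruePhysiology",
    "EffectConfig",
    "SessionPrescription",
    "RawBattery",
    "MIT_SESSION_ORDER",
    "HIT_SESSION_ORDER",
    "generate_cohort",
    "default_effect_config",
    "apply_block_effects",
    "simulate_step_test",
    "simulate_session",
    "simulate_vo2max_test",
    "simulate_sprint",
    "simulate_time_trial",
    "simulate_battery",
    "simulate_study",
    "simulate_vo2max_dose_response",
    "first_order_response",
    "true_po_at_lactate",
    "block_work_minutes",
    "prescription",
    "rng_for",
]

VO2_REST_L_MIN = 0.30  # resting oxygen uptake floor for the demand model

# sub-stream purpose codes
_COHORT, _EFFECTS, _STEPTEST, _SESSION, _TRIAL = 0, 1, 2, 3, 4


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic generator for a (seed, purpose, participant, ...) key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Participant:
    id: str
    sex: str            # "F" or "M"
    body_mass: float    # kg (baseline)
    height: float       # cm

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")


@dataclass(frozen=True)
class TruePhysiology:
    """Latent state whose observable consequences the test battery measures.

    The lactate–power curve is exponential plus baseline,
    La(P) = la_basal + la_amp · exp(la_rate · (P − po_4mmol_true)), with
    la_amp = 4 − la_basal so the curve crosses 4 mmol·L⁻¹ exactly at
    po_4mmol_true.  V̇O₂ responds to power demand as a single first-order
    system with time constant vo2_tau (no slow component).
    """

    vo2max_rel: float       # mL/min/kg
    ge_true: float          # fraction, gross efficiency
    la_basal: float         # mmol/L
    la_amp: float           # mmol/L
    la_rate: float          # 1/W
    hr_max: float           # bpm
    hr_rest: float          # bpm
    hr_slope: float         # bpm/W
    vo2_tau: float          # s
    po_40min_true: float    # W, 40-min maximal sustainable power
    po_4mmol_true: float    # W
    po_vo2max_true: float   # W
    po_15min_true: float    # W
    po_10sec_true: float    # W
    body_mass: float        # kg, current (block effects may shift it)
    fatigue_vo2_factor: float = 1.03  # V̇O₂ inflation in the semi-fatigued state

    def __post_init__(self) -> None:
        if not 0.15 <= self.ge_true <= 0.25:
            raise ValueError(f"ge_true {self.ge_true} outside [0.15, 0.25]")
        if self.la_amp <= 0 or self.la_rate <= 0 or self.vo2_tau <= 0:
            raise ValueError("la_amp, la_rate and vo2_tau must be positive")

    @property
    def vo2max_abs(self) -> float:
        """Absolute V̇O₂max in L/min."""
        return self.vo2max_rel * self.body_mass / 1000.0

    def lactate_at(self, power) -> np.ndarray:
        p = np.asarray(power, dtype=float)
        return self.la_basal + self.la_amp * np.exp(self.la_rate * (p - self.po_4mmol_true))

    def rer_at(self, power) -> np.ndarray:
        p = np.asarray(power, dtype=float)
        return np.clip(0.82 + 0.20 * p / self.po_vo2max_true, 0.75, 1.10)

    def vo2_demand_l_min(self, power, cap: bool = True) -> np.ndarray:
        """Steady-state V̇O₂ (L/min) implied by power and gross efficiency."""
        p = np.asarray(power, dtype=float)
        eq = 4840.0 * np.minimum(self.rer_at(p), 1.0) + 16890.0
        demand = np.maximum(VO2_REST_L_MIN, p * 60.0 / (self.ge_true * eq))
        if cap:
            demand = np.minimum(demand, self.vo2max_abs)
        return demand


def true_po_at_lactate(phys: TruePhysiology, level: float) -> float:
    """Closed-form root of the latent lactate curve at a given level (W)."""
    if level <= phys.la_basal:
        raise ValueError(f"level {level} at or below basal lactate {phys.la_basal}")
    return phys.po_4mmol_true + math.log((level - phys.la_basal) / phys.la_amp) / phys.la_rate


@dataclass
class EffectConfig:
    """True block effects and measurement-noise levels.

    ``blocks`` maps a block label to per-outcome (mean, SD) of the true
    individual percent change; the gross-efficiency entry ``ge_pp`` is in
    %-points.  ``drift`` (if present) models the washout period between
    blocks the same way.  Noise SDs apply to every simulated measurement.
    """

    blocks: dict[str, dict[str, tuple[float, float]]]
    lactate_sd: float = 0.2   # mmol/L
    vo2_pct: float = 2.0      # % multiplicative
    power_pct: float = 1.0    # %
    hr_sd: float = 3.0        # bpm
    rer_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for b, eff in self.blocks.items():
            for k, (mean, sd) in eff.items():
                if sd < 0:
                    raise ValueError(f"{b}/{k}: effect SD must be non-negative")
                if k != "ge_pp" and mean <= -100.0:
                    raise ValueError(f"{b}/{k}: percent effect {mean} must exceed -100")
        for name in ("lactate_sd", "vo2_pct", "power_pct", "hr_sd", "rer_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise {name} must be non-negative")


def default_effect_config(seed: int = 0) -> EffectConfig:
    """Study-condition defaults: per-block true effects with between-rider SDs.

    MIT/HIT means and SDs follow the reported individual percent changes
    (e.g. PO_4mmol +4.5 (4.5)% MIT vs +2.1 (2.7)% HIT); 'drift' reproduces
    the small shift in baselines over the ~2-month washout between blocks.
    """
    return EffectConfig(
        blocks={
            "MIT": {
                "po_4mmol": (4.5, 4.5),
                "po_vo2max": (2.4, 4.4),
                "po_15min": (4.9, 8.7),
                "po_10sec": (-1.5, 7.3),
                "vo2max": (1.6, 3.9),
                "ge_pp": (0.30, 0.55),
                "body_mass": (0.3, 0.8),
            },
            "HIT": {
                "po_4mmol": (2.1, 2.7),
                "po_vo2max": (3.7, 3.0),
                "po_15min": (2.8, 5.3),
                "po_10sec": (1.5, 3.7),
                "vo2max": (2.4, 3.9),
                "ge_pp": (0.22, 0.40),
                "body_mass": (0.3, 0.8),
            },
            "drift": {
                "po_4mmol": (2.8, 3.0),
                "po_vo2max": (0.3, 3.0),
                "po_15min": (4.4, 4.0),
                "po_10sec": (1.0, 3.0),
                "vo2max": (2.3, 3.0),
                "ge_pp": (0.0, 0.3),
                "body_mass": (0.6, 1.0),
            },
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_physiology(rng: np.random.Generator, body_mass: float) -> TruePhysiology:
    vo2max_rel = float(np.clip(rng.normal(69.5, 6.0), 50.0, 90.0))
    ge = float(np.clip(rng.normal(0.200, 0.012), 0.16, 0.24))
    frac4 = float(np.clip(rng.normal(0.792, 0.038), 0.60, 0.92))
    vo2max_abs = vo2max_rel * body_mass / 1000.0  # L/min
    eq_p4 = 4840.0 * 0.95 + 16890.0               # equivalent near threshold
    # floor keeps the weakest draws inside the well-trained range the 125-W
    # protocol start presumes (at least 3 completed steps before 4 mmol/L)
    po_4mmol = max(frac4 * vo2max_abs / 60.0 * ge * eq_p4, 200.0)
    ratio = float(np.clip(rng.normal(0.670, 0.025), 0.58, 0.78))
    # keep the ramp's end-demand at least 10% above V̇O₂max so the plateau is
    # always attained during the incremental test (true of maximal tests)
    ratio = min(ratio, frac4 / 1.10)
    po_vo2max = po_4mmol / ratio
    # strictly above threshold power: a 15-min maximal effort sits in the
    # severe domain for this population
    po_15min = po_4mmol * float(np.clip(rng.normal(1.040, 0.030), 1.005, 1.15))
    po_40min = po_4mmol * float(np.clip(rng.normal(1.020, 0.020), 0.95, 1.10))
    po_10sec = float(np.clip(rng.normal(13.51, 1.20), 8.0, 20.0)) * body_mass
    la_basal = float(np.clip(rng.normal(0.9, 0.15), 0.5, 1.4))
    la_rate = float(np.clip(rng.normal(0.025, 0.004), 0.012, 0.040))
    hr_max = float(np.clip(rng.normal(195.0, 7.0), 170.0, 215.0))
    hr_rest = float(np.clip(rng.normal(52.0, 5.0), 38.0, 70.0))
    hr_slope = (0.88 * hr_max - hr_rest) / po_40min
    vo2_tau = float(np.clip(rng.normal(30.0, 5.0), 15.0, 50.0))
    fatigue = float(np.clip(rng.normal(1.030, 0.012), 1.0, 1.08))
    return TruePhysiology(
        vo2max_rel=vo2max_rel,
        ge_true=ge,
        la_basal=la_basal,
        la_amp=4.0 - la_basal,
        la_rate=la_rate,
        hr_max=hr_max,
        hr_rest=hr_rest,
        hr_slope=hr_slope,
        vo2_tau=vo2_tau,
        po_40min_true=po_40min,
        po_4mmol_true=po_4mmol,
        po_vo2max_true=po_vo2max,
        po_15min_true=po_15min,
        po_10sec_true=po_10sec,
        body_mass=body_mass,
        fatigue_vo2_factor=fatigue,
    )


def generate_cohort(n: int, seed: int) -> list[tuple[Participant, TruePhysiology]]:
    """Draw n riders with latent physiology; deterministic given seed.

    Mirrors the study cohort: body mass ~ N(70.8, 7.9) kg, height
    ~ N(181, 7) cm, V̇O₂max ~ N(69.5, 6.0) mL·min⁻¹·kg⁻¹, one female rider
    (sex differences enter only through the drawn parameters).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out = []
    for i in range(n):
        rng = rng_for(seed, _COHORT, i)
        mass = float(np.clip(rng.normal(70.8, 7.9), 45.0, 100.0))
        height = float(np.clip(rng.normal(181.0, 7.0), 150.0, 205.0))
        sex = "F" if (i == 0 and n >= 2) else "M"
        p = Participant(id=f"P{i + 1:02d}", sex=sex, body_mass=mass, height=height)
        out.append((p, _draw_physiology(rng, mass)))
    return out


def apply_block_effects(
    phys: TruePhysiology,
    cfg: EffectConfig,
    block: str,
    rng: np.random.Generator,
) -> TruePhysiology:
    """Scale each latent parameter by a drawn individual percent change.

    Draws are N(mean, SD) per outcome, truncated at -95% so latent values
    stay positive; gross efficiency moves by a drawn %-point amount.
    """
    if block not in cfg.blocks:
        raise ValueError(f"block {block!r} not configured; have {sorted(cfg.blocks)}")
    eff = cfg.blocks[block]
    keys = ("po_4mmol", "po_vo2max", "po_15min", "po_10sec", "vo2max", "ge_pp", "body_mass")
    z = {k: rng.standard_normal() for k in keys}
    # ramp-maximum power gains co-move with V̇O₂max gains (shared central
    # adaptation); the correlation leaves each marginal at its configured
    # mean/SD but keeps the ramp test's end-demand above the V̇O₂ ceiling
    rho = 0.7
    z["po_vo2max"] = rho * z["vo2max"] + math.sqrt(1 - rho**2) * z["po_vo2max"]

    def factor(key: str) -> float:
        if key not in eff:
            return 1.0
        mean, sd = eff[key]
        return 1.0 + max(mean + sd * z[key], -95.0) / 100.0

    ge_post = phys.ge_true
    if "ge_pp" in eff:
        mean, sd = eff["ge_pp"]
        ge_post = float(np.clip(phys.ge_true + (mean + sd * z["ge_pp"]) / 100.0, 0.15, 0.25))
    # configured power effects are per-kg percent changes (the convention the
    # outcomes are reported in); absolute watts therefore scale by the mass
    # factor as well
    fm = factor("body_mass")
    f4 = factor("po_4mmol") * fm
    return replace(
        phys,
        po_4mmol_true=phys.po_4mmol_true * f4,
        po_40min_true=phys.po_40min_true * f4,
        po_vo2max_true=phys.po_vo2max_true * factor("po_vo2max") * fm,
        po_15min_true=phys.po_15min_true * factor("po_15min") * fm,
        po_10sec_true=phys.po_10sec_true * factor("po_10sec") * fm,
        vo2max_rel=phys.vo2max_rel * factor("vo2max"),
        ge_true=ge_post,
        body_mass=phys.body_mass * fm,
    )


# ---------------------------------------------------------------------------
# step test


def simulate_step_test(
    phys: TruePhysiology,
    participant: Participant,
    protocol: Optional[StepProtocolSpec] = None,
    noise: Optional[EffectConfig] = None,
    rng: Optional[np.random.Generator] = None,
    max_steps: int = 30,
) -> LactateProfile:
    """Run the incremental protocol against the latent lactate/V̇O₂ curves.

    Termination follows the protocol rules applied to the *measured* lactate
    values.  With zero noise, the interpolated 4-mmol·L⁻¹ power recovers the
    closed-form root of the latent curve up to chord error of the step grid.
    A curve that never reaches 4 mmol·L⁻¹ within ``max_steps`` yields a
    profile flagged ``terminated=False``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    la_sd = noise.lactate_sd if noise else 0.0
    vo2_pct = noise.vo2_pct if noise else 0.0
    rer_sd = noise.rer_sd if noise else 0.0
    hr_sd = noise.hr_sd if noise else 0.0
    if protocol is None:
        start = HIGH_START_POWER if phys.po_4mmol_true > 325.0 else 125.0
        protocol = StepProtocolSpec(start_power=start)
    steps: list[LactateStep] = []
    for _ in range(max_steps):
        p = next_step_power(steps, protocol)
        if p is None:
            return LactateProfile(participant.id, steps, terminated=True)
        la = float(phys.lactate_at(p)) + rng.normal(0.0, la_sd)
        la = max(la, 0.0)
        rer_true = float(phys.rer_at(p))
        vo2_true = float(phys.vo2_demand_l_min(p, cap=False)) * 1000.0  # mL/min
        vo2 = vo2_true * (1.0 + rng.normal(0.0, vo2_pct / 100.0))
        rer = float(np.clip(rer_true + rng.normal(0.0, rer_sd), 0.7, 1.2))
        hr = float(min(phys.hr_rest + phys.hr_slope * p + rng.normal(0.0, hr_sd), phys.hr_max))
        steps.append(LactateStep(power=p, lactate=la, vo2=max(vo2, 0.0), rer=rer, hr=hr))
    return LactateProfile(participant.id, steps, terminated=False)


# ---------------------------------------------------------------------------
# kinetics and sessions


def first_order_response(
    demand: np.ndarray, dt: float, tau: float, v0: float = VO2_REST_L_MIN
) -> np.ndarray:
    """Exact first-order response to a piecewise-constant demand sequence.

    v[k] = d[k] + (v[k-1] − d[k])·exp(−dt/τ): matches the analytic
    exponential at every sample when demand is constant within a sample.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    a = math.exp(-dt / tau)
    demand = np.asarray(demand, dtype=float)
    out, _ = lfilter([1.0 - a], [1.0, -a], demand, zi=[a * v0])
    return out


@dataclass(frozen=True)
class SessionPrescription:
    """Shape of one interval session, intensities as fractions of 40-min power."""

    name: str
    kind: str                 # "MIT" or "HIT"
    n_intervals: int
    work_s: float
    recovery_s: float
    work_intensity: float = 0.94      # MIT: continuous fraction of po_40min
    hi_intensity: float = 1.18        # HIT 30-s on
    lo_intensity: float = 0.60        # HIT 15-s off
    on_s: float = 30.0
    off_s: float = 15.0
    recovery_intensity: float = 0.40
    rpe_target: float = 14.5
    srpe_target: float = 5.0


_PRESCRIPTIONS = {
    "7x10": SessionPrescription("7x10", "MIT", 7, 600.0, 150.0),
    "6x12": SessionPrescription("6x12", "MIT", 6, 720.0, 180.0),
    "5x14": SessionPrescription("5x14", "MIT", 5, 840.0, 210.0),
    "5x8.75": SessionPrescription(
        "5x8.75", "HIT", 5, 525.0, 180.0, rpe_target=17.1, srpe_target=6.9
    ),
}

#: Session order within each block (first and fourth MIT sessions are 7 × 10 min, ...).
MIT_SESSION_ORDER = ("7x10", "6x12", "5x14", "7x10", "5x14", "6x12")
HIT_SESSION_ORDER = ("5x8.75",) * 5

#: Sessions with gas-exchange measurement (0-based): second and last of each block.
GAS_SESSIONS = {"MIT": (1, 5), "HIT": (1, 4)}


def prescription(name: str) -> SessionPrescription:
    if name not in _PRESCRIPTIONS:
        raise ValueError(f"unknown prescription {name!r}; known: {sorted(_PRESCRIPTIONS)}")
    return _PRESCRIPTIONS[name]


def block_work_minutes(block: str) -> float:
    """Total prescribed work-interval minutes of a block."""
    order = {"MIT": MIT_SESSION_ORDER, "HIT": HIT_SESSION_ORDER}[block]
    return sum(prescription(s).n_intervals * prescription(s).work_s for s in order) / 60.0


def _session_power_profile(
    phys: TruePhysiology, rx: SessionPrescription, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample prescribed power and segment labels (warm-up + intervals)."""
    p40 = phys.po_40min_true
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def add(power: np.ndarray, label: str) -> None:
        chunks.append(power)
        labels.append(np.full(power.shape, label, dtype=object))

    n_wu = int(round(900.0 / dt))  # 15-min progressive warm-up
    add(p40 * np.linspace(0.35, 0.70, n_wu), "warmup")
    add(np.full(int(round(300.0 / dt)), 0.0), "rest")  # 5 min rest before intervals
    for k in range(rx.n_intervals):
        n_w = int(round(rx.work_s / dt))
        if rx.kind == "MIT":
            work = np.full(n_w, rx.work_intensity * p40)
        else:
            t = np.arange(n_w) * dt
            phase = np.mod(t, rx.on_s + rx.off_s)
            work = np.where(phase < rx.on_s, rx.hi_intensity * p40, rx.lo_intensity * p40)
            # riders adjust the short intervals dynamically toward RPE 16-18,
            # ramping in and finishing hard within each 8.75-min interval
            work = work * np.linspace(0.97, 1.13, n_w)
        add(work, f"work-{k + 1}")
        if k < rx.n_intervals - 1:
            n_r = int(round(rx.recovery_s / dt))
            add(np.full(n_r, rx.recovery_intensity * p40), f"recovery-{k + 1}")
    return np.concatenate(chunks), np.concatenate(labels)


def simulate_session(
    phys: TruePhysiology,
    participant: Participant,
    rx: SessionPrescription | str,
    rng: np.random.Generator,
    noise: Optional[EffectConfig] = None,
    sample_period: float = 10.0,
    measure_gas: bool = True,
) -> tuple[GasSeries, list[float], float]:
    """One interval session: 10-s-sampled series plus per-interval RPE and sRPE.

    V̇O₂ follows first-order kinetics toward the demand implied by
    instantaneous power and gross efficiency (capped at V̇O₂max); HR is
    linear in first-order-smoothed power, saturating at HRmax.
    """
    if isinstance(rx, str):
        rx = prescription(rx)
    power, labels = _session_power_profile(phys, rx, sample_period)
    vo2_pct = noise.vo2_pct if noise else 0.0
    pow_pct = noise.power_pct if noise else 0.0
    hr_sd = noise.hr_sd if noise else 0.0
    rer_sd = noise.rer_sd if noise else 0.0
    power_actual = power * (1.0 + rng.normal(0.0, pow_pct / 100.0, power.size))
    demand = phys.vo2_demand_l_min(power_actual)
    vo2_true = first_order_response(demand, sample_period, phys.vo2_tau)
    p_smooth = first_order_response(power_actual, sample_period, 40.0, v0=0.0)
    hr = np.minimum(phys.hr_rest + phys.hr_slope * p_smooth, phys.hr_max)
    hr = hr + rng.normal(0.0, hr_sd, hr.size)
    if measure_gas:
        vo2 = vo2_true * 1000.0 * (1.0 + rng.normal(0.0, vo2_pct / 100.0, vo2_true.size))
        rer = np.clip(phys.rer_at(p_smooth) + rng.normal(0.0, rer_sd, p_smooth.size), 0.7, 1.2)
    else:
        vo2 = np.full(power.size, np.nan)
        rer = np.full(power.size, np.nan)
    series = GasSeries(
        sample_period=sample_period,
        power=power_actual,
        vo2=np.maximum(vo2, 0.0) if measure_gas else vo2,
        rer=rer,
        hr=hr,
        segments=labels,
    )
    rpe = [float(np.clip(rx.rpe_target + rng.normal(0.0, 0.3), 6.0, 20.0))
           for _ in range(rx.n_intervals)]
    srpe = float(np.clip(rx.srpe_target + rng.normal(0.0, 0.5), 0.0, 10.0))
    return series, rpe, srpe


# ---------------------------------------------------------------------------
# battery trials


def simulate_vo2max_test(
    phys: TruePhysiology,
    participant: Participant,
    rng: np.random.Generator,
    noise: Optional[EffectConfig] = None,
    sample_period: float = 5.0,
) -> GasSeries:
    """Incremental ramp to exhaustion, 5-s sampling.

    Start/increment: 250 W + 25 W·min⁻¹ for males, 160 W + 20 W·min⁻¹ for
    females.  Exhaustion is placed so the mean power of the final minute
    equals the latent PO_V̇O₂max (up to the 5-s grid)."""
    start, inc = (160.0, 20.0) if participant.sex == "F" else (250.0, 25.0)
    target = phys.po_vo2max_true
    j = max(int(math.floor((target - start) / inc)), 1)
    f = (target - start - inc * j) / inc
    f = min(max(f, 0.0), 0.999)
    n_partial = int(round(f * 60.0 / sample_period))
    minutes = [np.full(int(60.0 / sample_period), start + inc * m) for m in range(j + 1)]
    if n_partial:
        minutes.append(np.full(n_partial, start + inc * (j + 1)))
    power = np.concatenate(minutes)
    demand = phys.vo2_demand_l_min(power)
    vo2_true = first_order_response(demand, sample_period, phys.vo2_tau, v0=0.8)
    vo2_pct = noise.vo2_pct if noise else 0.0
    hr_sd = noise.hr_sd if noise else 0.0
    vo2 = vo2_true * 1000.0 * (1.0 + rng.normal(0.0, vo2_pct / 100.0, vo2_true.size))
    rer = np.clip(phys.rer_at(power), 0.75, 1.2)
    p_smooth = first_order_response(power, sample_period, 40.0, v0=0.0)
    hr = np.minimum(phys.hr_rest + phys.hr_slope * p_smooth * 1.02, phys.hr_max)
    hr = hr + rng.normal(0.0, hr_sd, hr.size)
    return GasSeries(sample_period=sample_period, power=power,
                     vo2=np.maximum(vo2, 0.0), rer=rer, hr=hr,
                     segments=np.full(power.size, "work-ramp", dtype=object))


def simulate_sprint(
    phys: TruePhysiology,
    participant: Participant,
    rng: np.random.Generator,
    noise: Optional[EffectConfig] = None,
    sample_period: float = 1.0,
) -> np.ndarray:
    """12-s all-out sprint power trace whose best 10-s mean is the latent PO_10sec."""
    shape = np.linspace(1.25, 0.75, 12)
    shape = shape / shape[:10].mean()
    pow_pct = noise.power_pct if noise else 0.0
    trace = phys.po_10sec_true * shape * (1.0 + rng.normal(0.0, pow_pct / 100.0, shape.size))
    return np.maximum(trace, 0.0)


def simulate_time_trial(
    phys: TruePhysiology,
    participant: Participant,
    rng: np.random.Generator,
    noise: Optional[EffectConfig] = None,
    sample_period: float = 10.0,
) -> GasSeries:
    """15-min maximal trial: self-paced around the latent PO_15min."""
    n = int(round(900.0 / sample_period))
    t = np.arange(n) * sample_period
    pacing = 1.0 + 0.03 * np.cos(2 * np.pi * t / 900.0)  # fast start, fade, end surge
    pacing /= pacing.mean()
    pow_pct = noise.power_pct if noise else 0.0
    vo2_pct = noise.vo2_pct if noise else 0.0
    hr_sd = noise.hr_sd if noise else 0.0
    power = phys.po_15min_true * pacing * (1.0 + rng.normal(0.0, pow_pct / 100.0, n))
    demand = phys.vo2_demand_l_min(power)
    vo2_true = first_order_response(demand, sample_period, phys.vo2_tau,
                                    v0=0.7 * float(demand[0]))
    vo2 = vo2_true * 1000.0 * (1.0 + rng.normal(0.0, vo2_pct / 100.0, n))
    rer = np.clip(phys.rer_at(power), 0.75, 1.2)
    p_smooth = first_order_response(power, sample_period, 40.0, v0=0.0)
    hr = np.minimum(phys.hr_rest + phys.hr_slope * p_smooth * 1.02, phys.hr_max)
    hr = hr + rng.normal(0.0, hr_sd, n)
    return GasSeries(sample_period=sample_period, power=power,
                     vo2=np.maximum(vo2, 0.0), rer=rer, hr=hr,
                     segments=np.full(n, "work-tt", dtype=object))


@dataclass
class RawBattery:
    """Raw inputs of one prolonged test battery, in protocol order."""

    profile: LactateProfile
    sprint_power: np.ndarray          # 1-s sampling
    vo2max_series: GasSeries          # 5-s sampling
    tired_steps: list[LactateStep]    # repeated 3rd/2nd-last steps, semi-fatigued
    time_trial: GasSeries             # 10-s sampling


def simulate_battery(
    phys: TruePhysiology,
    participant: Participant,
    rng: np.random.Generator,
    noise: Optional[EffectConfig] = None,
) -> RawBattery:
    """Simulate the full prolonged battery for one rider at one timepoint."""
    profile = simulate_step_test(phys, participant, noise=noise, rng=rng)
    sprint = simulate_sprint(phys, participant, rng, noise)
    vmax = simulate_vo2max_test(phys, participant, rng, noise)
    # 30-min bout at the 2-mmol power, then the 3rd and 2nd last steps repeated
    # semi-fatigued: V̇O₂ inflated by the rider's fatigue factor.
    tired: list[LactateStep] = []
    vo2_pct = noise.vo2_pct if noise else 0.0
    rer_sd = noise.rer_sd if noise else 0.0
    hr_sd = noise.hr_sd if noise else 0.0
    la_sd = noise.lactate_sd if noise else 0.0
    for s in profile.steps[-3:-1]:
        vo2_true = float(phys.vo2_demand_l_min(s.power, cap=False)) * 1000.0
        vo2 = vo2_true * phys.fatigue_vo2_factor * (1.0 + rng.normal(0.0, vo2_pct / 100.0))
        rer = float(np.clip(phys.rer_at(s.power) + rng.normal(0.0, rer_sd), 0.7, 1.2))
        la = max(float(phys.lactate_at(s.power)) + rng.normal(0.0, la_sd), 0.0)
        hr = float(min(phys.hr_rest + phys.hr_slope * s.power + 4.0 + rng.normal(0.0, hr_sd),
                       phys.hr_max))
        tired.append(LactateStep(power=s.power, lactate=la, vo2=vo2, rer=rer, hr=hr))
    tt = simulate_time_trial(phys, participant, rng, noise)
    return RawBattery(profile=profile, sprint_power=sprint, vo2max_series=vmax,
                      tired_steps=tired, time_trial=tt)


# ---------------------------------------------------------------------------
# whole-study simulation


def simulate_study(
    n: int, seed: int, cfg: Optional[EffectConfig] = None
) -> list[dict]:
    """Latent states for the two-period design: pre/post MIT, washout drift, pre/post HIT.

    Returns one record per rider: participant plus a dict of TruePhysiology
    keyed by (block, timepoint)."""
    cfg = cfg if cfg is not None else default_effect_config(seed)
    cohort = generate_cohort(n, seed)
    records = []
    for i, (part, base) in enumerate(cohort):
        rng = rng_for(seed, _EFFECTS, i)
        post_mit = apply_block_effects(base, cfg, "MIT", rng)
        pre_hit = apply_block_effects(base, cfg, "drift", rng) if "drift" in cfg.blocks else base
        post_hit = apply_block_effects(pre_hit, cfg, "HIT", rng)
        records.append(
            {
                "participant": part,
                "phys": {
                    ("MIT", "pre"): base,
                    ("MIT", "post"): post_mit,
                    ("HIT", "pre"): pre_hit,
                    ("HIT", "post"): post_hit,
                },
            }
        )
    return records


def simulate_vo2max_dose_response(
    n: int,
    seed: int,
    slope: float = 0.41,
    intercept: float = -2.0,
    noise_sd: float = 2.3,
) -> "pd.DataFrame":
    """Riders whose V̇O₂max change depends linearly on minutes ≥ 90% of V̇O₂max.

    Built-in truth for regression-recovery checks: Δvo2max = intercept +
    slope·minutes + 0.05·baseline − 0.5·Δmass + N(0, noise_sd).  Minutes are
    drawn to match the high-intensity block's spread (~10.7 (7.7) min).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    minutes = np.clip(rng.normal(10.7, 7.7, n), 0.0, None)
    baseline = rng.normal(69.5, 6.0, n)
    d_mass = rng.normal(0.2, 0.6, n)
    dvo2 = intercept + slope * minutes + 0.05 * baseline - 0.5 * d_mass + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "minutes_ge90": minutes,
            "baseline_vo2max": baseline,
            "delta_body_mass": d_mass,
            "delta_vo2max": dvo2,
        }
    )
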