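"""Interval-session load: %V̇O₂max, time ≥ 90% V̇O₂max, energy turnover, TRIMP.

Simulates a moderate-intensity session (7 × 10 min continuous) and a
high-intensity session (5 × 8.75 min of 30/15-s intervals) for the same
rider and summarizes both the way a training-load table would.
"""

import numpy as np
import pandas as pd

import cyclephys as cp
from cyclephys import cohort as syn
from cyclephys.load import summarize_session, summarize_week

part, phys = syn.generate_cohort(3, seed=42)[1]
cfg = syn.default_effect_config(0)

for name in ("7x10", "5x8.75"):
    series, rpe, srpe = syn.simulate_session(phys, part, name, np.random.default_rng(1), cfg)
    s = summarize_session(
        series, participant_id=part.id,
        vo2max=phys.vo2max_abs * 1000, hr_max=phys.hr_max,
        po_vo2max_ref=phys.po_vo2max_true, body_mass=part.body_mass,
        rpe_per_interval=rpe, srpe=srpe,
    )
    kind = "MIT" if name != "5x8.75" else "HIT"
    print(f"{kind} {name}: PO {s.po_w_kg:.2f} W/kg, {s.pct_vo2max:.1f}% V̇O₂max, "
          f"{s.pct_hr_max:.1f}% HRmax, t≥90%V̇O₂max {s.time_ge90_vo2max_s / 60:.1f} min, "
          f"energy {s.energy_total_kj:.0f} kJ, RPE {s.rpe_mean:.1f}")

log = pd.DataFrame(
    [("P", "endurance", z, m, 5.0) for z, m in [(1, 270), (2, 290), (3, 240), (4, 340), (5, 30)]],
    columns=["participant_id", "activity", "zone_or_percent", "duration_min", "feeling_legs"],
)
week = summarize_week(log)
print(f"\nweek: {week.total_min / 60:.1f} h endurance, TRIMP {week.trimp:.0f}")
print("Higher zones multiply minutes by the zone number, so the same hours at")
print("higher intensity score a larger training impulse.")
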