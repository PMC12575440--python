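"""Incremental step test: threshold power and fractional utilization.

Simulates one rider's blood-lactate profile test (5.5-min steps, +50 W until
2 mmol/L, then +25 W until 4 mmol/L), then interpolates the 4-mmol power and
the %V̇O₂max at that power.
"""

import numpy as np

import cyclephys as cp
from cyclephys import cohort as syn

part, phys = syn.generate_cohort(3, seed=42)[1]
rng = np.random.default_rng(0)
profile = syn.simulate_step_test(phys, part, noise=syn.default_effect_config(0), rng=rng)

print(f"rider {part.id}: {part.body_mass:.1f} kg, latent threshold {phys.po_4mmol_true:.0f} W")
print("step  power_W  lactate  vo2_L_min")
for s in profile.steps:
    print(f"      {s.power:6.0f}  {s.lactate:7.2f}  {s.vo2 / 1000:9.2f}")

po4 = cp.po_at_lactate(profile, 4.0)
vo2max = phys.vo2max_abs * 1000  # would come from the ramp test in a full battery
frac = cp.fractional_utilization_at_power(profile, vo2max, po4)
print(f"\nPO_4mmol  = {po4:.1f} W ({po4 / part.body_mass:.2f} W/kg)")
print(f"%V̇O₂max at PO_4mmol = {frac:.1f}%")
print("The interpolated threshold sits between the last two steps; the")
print("fractional utilization says how much of the rider's aerobic ceiling")
print("that workload demands.")
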