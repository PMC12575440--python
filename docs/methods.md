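# Methods

This note documents the models, parameter choices and numerical decisions
behind `cyclephys`, and what the synthetic cohort does and does not emulate.

## Measurement models

### Lactate profile

Thresholds are read off the step test by piecewise-linear interpolation
between the two steps bracketing the target level. "Linear regression
between data points" is implemented as local segments, not a global line: a
single regression line cannot represent a convex lactate–power curve, and
only the bracketing pair determines the crossing. Consequences:

- No extrapolation, ever. A profile that never reaches the level (or starts
  above it) raises `NotBracketedError`; callers needing the 2-mmol·L⁻¹ power
  for the 30-min bout use the same rule.
- An exact hit returns that step's power; under a zero-slope (tied) segment
  the lowest bracketing power is returned — the conservative threshold.
- Fractional utilization interpolates per-step %V̇O₂max against power with
  the same bracketing restriction.
- The chord of a convex curve lies above it, so the interpolated 4-mmol
  power sits slightly below the true crossing — bounded by one fine
  increment (25 W) and shrinking with denser steps. Pre/post changes cancel
  most of this bias.

### Gas exchange

The energetic equivalent of oxygen is linear in RER
(4840·RER + 16890 J·L⁻¹). Above RER 1.0 the equivalent is undefined (net
anaerobic CO₂ excess), so RER is clamped at 1.0 and values outside
[0.6, 1.3] are rejected as sensor error. Gross efficiency is
GE = 100·PO/PI — mechanical power as a share of metabolic power, the
orientation that yields the expected ≈ 20% for trained cyclists.

V̇O₂max is the best 60-s rolling mean; the window is defined in seconds, so
5-s test sampling uses 12 samples and 10-s session sampling uses 6. Session
summaries (mean %V̇O₂max, %HRmax, power, energy turnover, time ≥ 90% of a
reference) are restricted to work-interval samples and duration-weighted;
time above a threshold counts samples ≥ fraction·reference times the sample
period. Whether recovery periods should count toward time ≥ 90% V̇O₂max is a
genuine protocol ambiguity; work-intervals-only is used because the quantity
describes load *during the interval series*.

### Training load

The printed five-zone ranges contain display-rounding gaps (…55 / 56…);
contiguous half-open bins [0,55), [55,75), [75,90), [90,105), [105,∞) with
each cut assigned upward make zone assignment a partition — every endurance
minute lands in exactly one zone, which TRIMP's linearity requires. Both a
power-based and an HR-based 40-min reference are supported; power is the
default and the choice is recorded in the run configuration.

### Performance index

The index normalizes PO_V̇O₂max, PO₄ₘₘₒₗ and PO₁₅ₘᵢₙ by their maxima over
the *pooled* reference set (both blocks, both timepoints) and averages the
three ratios. Pooling is the natural reading of "maximum observed across all
participants" in a within-subject two-block design; because the basis is
stored with results, any alternative reference set reproduces exactly. The
index is scale-invariant per indicator and strictly increasing in each
rider's own values.

### Change analysis

The between-block comparison replaces a REML mixed model + marginal-means
contrast with an exactly equivalent (for complete, balanced two-period data)
baseline-adjusted paired analysis: with per-rider change scores Δᴬᵢ, Δᴮᵢ and
baselines bᴬᵢ, bᴮᵢ, regress dᵢ = Δᴬᵢ − Δᴮᵢ on the centred covariate
xᵢ = bᴬᵢ − bᴮᵢ; the intercept estimates the block×time contrast and is
tested on n − 2 df. This preserves the contrast of interest without
re-implementing REML; under missingness the p-values would diverge from the
mixed model's, so the implementation analyzes completed cases only and
reports exclusions. With fewer than three complete pairs the covariate is
dropped (plain paired contrast).

Cohen's d uses the two-sample pooled-SD form on percent changes (%-point
changes for gross efficiency and fractional utilization, routed by outcome
metadata), interpreted on the Rhea cuts 0.25/0.5/1.0 for highly trained
subjects. The design is within-subject, so the paired standardized mean
difference d_z is computed alongside and labeled as such; the two-sample d
remains the primary, scale-compatible statistic. Significance is two-sided
p ≤ 0.05 with no multiplicity correction. Percent changes are means of
per-rider percentages; the ratio of group means is a different quantity and
both are available (the printed-table arithmetic uses group means, labeled
accordingly).

Regressions are ordinary least squares with baseline and Δbody-mass (and
optionally sex) covariates; adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
Rank-deficient designs raise an error naming the offending columns — a
constant predictor (e.g. zero minutes ≥ 90% V̇O₂max in every
moderate-intensity session) is reported rather than silently fit.

## Synthetic cohort

Each rider carries a latent state: V̇O₂max, gross efficiency, an
exponential-plus-baseline lactate curve
La(P) = La_b + (4 − La_b)·exp(r·(P − P₄)) anchored so it crosses 4 mmol·L⁻¹
exactly at the latent threshold power, a linear HR response saturating at
HRmax, and single first-order V̇O₂ kinetics (exact discrete recursion, so a
square-wave demand reproduces the analytic exponential at every sample).

Key defaults (chosen once to match the study cohort and field-typical
measurement error; not tuned afterwards):

| parameter | default | rationale |
|---|---|---|
| V̇O₂max | N(69.5, 6.0) mL·min⁻¹·kg⁻¹ | cohort descriptor |
| body mass | N(70.8, 7.9) kg | cohort descriptor |
| gross efficiency | N(0.200, 0.012), clamped [0.16, 0.24] | reproduces GE ≈ 19.6–20% at the profile steps |
| fractional utilization at P₄ | N(0.792, 0.038) | reproduces %V̇O₂max at PO₄ₘₘₒₗ ≈ 79% |
| P₄ / PO_V̇O₂max ratio | N(0.670, 0.025) | reproduces the 3.96 / 5.91 W·kg⁻¹ pair |
| lactate curve rate r | N(0.025, 0.004) W⁻¹ | doubles lactate every ~30 W above threshold |
| V̇O₂ time constant τ | N(30, 5) s | trained-cyclist on-kinetics |
| noise: lactate 0.2 mmol·L⁻¹, V̇O₂ 2%, power 1%, HR 3 bpm | — | analyzer/metabolic-cart/power-meter precision |

Individual distributions are normal with physiological clamps — the source
tables report only means (SD), so shapes are an assumption, not an
inference. A floor of 200 W on the latent threshold keeps the weakest draws
inside the well-trained range the 125-W protocol start presumes. Block
effects are drawn per rider as percent changes (mean, SD per block; %-points
for efficiency) and apply to *per-kg* outcomes — the convention results are
reported in — so absolute watts also scale with the body-mass factor. Ramp
power gains are correlated with V̇O₂max gains (ρ = 0.7, marginals
preserved): central adaptations move both, and the correlation keeps the
ramp's end-demand above the V̇O₂ ceiling so the plateau is always attained.
A "drift" pseudo-block reproduces the small baseline shift over the washout
between blocks. All randomness flows through SeedSequence sub-streams keyed
by (seed, purpose, rider), so one seed fixes everything and adding riders
never perturbs existing ones.

Sessions follow the prescribed shapes (7×10, 6×12, 5×14-min continuous;
5 × 8.75-min of 30/15-s intervals at ~118/60% of 40-min power, with a
within-interval ramp to ~113% of guide power emulating RPE-guided pacing).
Demand is capped at V̇O₂max; first-order kinetics plus 10-s sampling then
produce the study's qualitative contrasts: higher %V̇O₂max, far more time
≥ 90% V̇O₂max, higher HR and RPE in the high-intensity block.

**What the generator does not emulate.** No V̇O₂ slow component — absolute
%V̇O₂max in the high-intensity sessions runs ~4 pp below the study's
(≈ 79 vs 83%) and time ≥ 90% V̇O₂max is shorter, though the between-block
ordering is robust. No cadence, drafting, environment, nutrition, illness or
dropout; RPE is a configured constant plus noise, not a psychophysical
model; no sex-specific kinetics (the one female rider differs only through
drawn parameters). Passing tests therefore demonstrate that the analysis
chain recovers known truth under realistic noise — not that the generator is
a complete physiological simulator.

## Numerical choices and degenerate inputs

- Rolling maxima use cumulative sums (O(n)); tests check them against
  exhaustive window scans.
- The V̇O₂max ramp ends so the final-minute mean equals the latent
  PO_V̇O₂max up to the 5-s grid; the measured best-60-s V̇O₂ then
  underestimates the latent ceiling by the kinetics tail (<1%), a bias that
  largely cancels in pre/post changes.
- A lactate curve that never reaches 4 mmol·L⁻¹ (degenerate flat curve, or
  step cap reached) yields a profile flagged non-terminating; downstream
  threshold queries fail loudly.
- Zero pooled SD makes Cohen's d undefined and raises — except the all-zero
  no-change case, which is reported as d = 0 (trivial).
- Pipeline records that fail validation are excluded one by one with logged
  reasons; the run continues and reports counts.

## Problem sizes

The test suite simulates cohorts of 4–22 riders and uses 100 replicate
cohorts for end-to-end recovery, 1000 replicates for the null calibration of
the block contrast, and 200 replicates for regression-slope recovery; the
acceptance script uses the same sizes. These give Monte-Carlo error well
inside the tolerances asserted (e.g. ±1.5 %-points on the 5% type-I rate)
while keeping the whole suite under a minute on one core.

## Known limitations

- The baseline-adjusted paired contrast equals the mixed-model contrast only
  for complete balanced data; with dropout the package excludes incomplete
  pairs rather than borrowing strength across riders.
- The printed total work duration of the high-intensity block ("3 h 42 min")
  is not reproducible from its prescription (5 × 5 × 8.75 min = 218.75 min ≈
  3 h 39 min); the package reports the prescription arithmetic.
- Group-mean percent changes differ from means of per-rider percent changes;
  both are computed, and users should match the convention of whatever
  numbers they compare against.
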