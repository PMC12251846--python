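# Methods

## Overview

The package couples three models: (1) a geometric model of a single
inhalation through a reusable soft-mist inhaler, (2) a Monte Carlo model of
how a cohort acquires the proper inhalation technique over a multi-year
training programme with smart (pressure-sensing) inhaler prototypes, and
(3) a deterministic budget-impact model that translates training outcomes
into 2024–2028 cohort costs and savings, in EUR and in Social-Cost-of-
Carbon (SCC) EUR.

## Inhalation geometry

A smart prototype senses the pressure drop Δp across the device; with a
dimensionless resistance R (default 1) the instantaneous inspiratory flow
is Q = Δp/R, so a sensed trace is a flow-time curve. Curves are condensed
into 18 samples (t_i, Q_i): flow starts at rest (Q_1 = 0), rises to the
Peak Inspiratory Flow (PIF) and decays toward zero. Consecutive samples
define segment slopes m_i = (Q_{i+1} − Q_i)/(t_{i+1} − t_i); the inhaled
volume is the trapezoidal area under the curve, Σ (t_{i+1} − t_i)(Q_i +
Q_{i+1})/2, with a 1/60 factor (times in seconds, flows in L/min, volumes
in litres). Ties for the maximum flow are broken toward the earliest index.

The manufacturer's moderate- and severe-COPD reference profiles are not
published as coordinates, so the package generates synthetic stand-ins:
a power-law rising limb Q(t) = PIF·(t/t_PIF)^r (r = 0.8, fast early
acceleration) and an exponential decay Q(t) = PIF·exp(−d·(t −
t_PIF)/(T − t_PIF)) (d = 2.5) on a uniform 18-point grid, with the
requested time-to-PIF snapped to the nearest grid point so exactly one
sample attains the PIF. Defaults: moderate PIF 35 L/min, t_PIF 0.8 s,
duration 2.5 s (volume 0.62 L); severe PIF 45 L/min, t_PIF 0.6 s, duration
2.2 s (volume 0.70 L) — severe COPD patients inhale harder and sharper
through this device type, consistent with their higher in-vitro delivery
rate (67.4 % vs 59.2 %). Only volumes *relative* to each severity's own
reference enter the simulation, so the absolute calibration of these
stand-ins does not affect the learned fractions; it does affect nothing
downstream of the cost model either, which consumes only percentages.

## Training Monte Carlo

Each of four models (moderate/severe × five-year/four-year training) runs
104,500 independent patients. Per training year a patient's slopes are
drawn Normal(m_i, |m_i|·cv), with separate coefficients of variation before
and after the PIF (flow timing is far more variable before the peak). The
perturbed slopes are propagated cumulatively — a deviation in slope i
shifts the starting flow of every later segment — and negative intermediate
flows are clamped to zero (inhalation cannot reverse), which skews the
simulated volume distribution slightly upward at high variability. The
simulated volume inhVsim is compared with the reference inhV.

The daily dose takes two consecutive inhalations, and the device reports
the first volume immediately: the patient deliberately corrects through the
second inhalation only when the first fell short. A year is *confirmed*
when either attempt reaches inhV (per-year probability 1 − (1 − q)² for
single-attempt success q). Confirmation multiplies both cv values by 0.9
(floored at 60 % of their initial values) and earns a delivery-rate gain;
a patient counts as having *learned* the technique only when every year of
the evaluation window is confirmed.

**Four-year window.** Both cohorts are evaluated over the same 2019–2023
window of the underlying budget-impact study. The four-year-trained cohort
spends 2019 untrained: the patient still inhales, but without device
feedback there is no information to trigger a corrective second inhalation,
so only a single attempt counts; variability does not decay and no gain is
earned (its reported 2019 gain is fixed at zero). This lead-in year is why
the shorter programme produces a *smaller* consistently-learned fraction
(≈23 %) than the longer one (≈32 %) even though it requires fewer assisted
confirmations: the five-year fraction is p⁵ while the four-year fraction is
q·p⁴ with q < p. Without the lead-in (configurable via
`TrainingConfig.lead_in_years = 0`) the four-year fraction would necessarily
exceed the five-year one (p⁴ > p⁵), contradicting the reported ordering —
with symmetric slope noise q ≥ ½, so p ≥ ¾ and a four-year product can
never reach 23 %. The lead-in mechanism is the package's resolution of that
tension and is documented here as a modelling choice.

**Calibration.** The magnitudes of the slope variability are not published,
only their ordering ("high-to-moderate" pre-PIF, "moderate-to-low" post).
With the structural ratios fixed (post-PIF cv = half the pre-PIF cv, decay
0.9, floors at 60 %), the initial pre-PIF cv was calibrated once by
bisection (`analysis/02_calibrate_variability.py`) so the pooled five-year
learned fraction hits 32 %; the four-year fraction then lands at ≈23 %
through the lead-in mechanism without further tuning. The calibrated value
(pre-PIF cv 2.03) is stored in the default config, not in code. A cv of
this size means individual segment slopes routinely overshoot or reverse,
which matches the high breath-to-breath variability reported for untrained
patients; at cv = 0 the model collapses to certain learning (inhVsim ≡
inhV, every year confirmed), a closed-form limit used in the tests.

**Delivery-rate gains.** Confirmed years add an increment drawn from a
normal with mean `max_final_gain / n_training_years` (so the cumulative
mean ramps linearly to the cap in the final year — the model assumes a
linear improvement of technique over the years) and SD 0.25 percentage
points, truncated to [0, remaining headroom]; the cumulative gain therefore
never exceeds +4.9 % (moderate) / +4.6 % (severe) over the 59.2 % / 67.4 %
baselines, and the working delivery rate lives on [baseline, baseline +
cap]. Reported mean gains average over learners only.

The engine is vectorised over runs (one seeded `numpy` Generator per
cohort model, sub-seeded deterministically from the top-level seed via
`SeedSequence`); the second attempt is drawn for every run and used only
where the first failed, which is distributionally identical to sequential
drawing. A full four-model study runs in a few seconds.

## Budget-impact model

The billing cohort is 94,050 patients — derived from the published
pattern-1/version-A annual cohort cost (64.5 M EUR at 12 × (42.96 + 1.87 +
12.32) = 685.8 EUR per patient-year), floored to whole patients. Treatment
patterns prescribe 12 cartridges per patient-year with 12, 6 or 4 inhaler
cases; a smart prototype adds one electronic module per case (design A
feature-rich, B high-performance, C lightweight).

A learner's cartridge content in post-training year 2024+k is reduced in
proportion to the gain of training year 2019+k (the phase-in rule), scaling
the cartridge's cost (42.96 EUR) and footprint (0.080 kg → 0.32 SCC cents)
linearly. The default policies (SR1/SR2/SR3) give everyone a smart inhaler
and price the cartridge as a learner-fraction blend; the alternative
policies (SR2M/SR3M) give smart inhalers with standard cartridges to
non-learners and regular inhalers with reduced cartridges to learners.
Savings are always measured against the all-smart standard-cartridge cost
of the same design version and pattern, so cost + savings = baseline holds
per year in both units. The projection defaults to learner fractions
0.32/0.23 and the published gain schedules, decoupling the deterministic
tables from the stochastic calibration; both can be redirected to the
simulator's outputs in config. Averages over 2024–2028 are unweighted
means. The simplified ICER against the reusable benchmark R (537.96 EUR
per patient-year under pattern 1) is the arithmetic mean-cost difference,
with no QALY denominator (equal clinical outcomes assumed).

**Reporting rounding.** Cartridge prices to 2 decimals (EUR) and 3 decimals
(SCC cents); cohort costs to 0.1 M EUR (annual) or 0.01 M EUR (means);
SCC cohort costs to thousands of EUR at 1–2 decimals. Rounding is applied
only at the reporting layer; all internal arithmetic is unrounded.

**Known inconsistency.** The published environmental cohort-cost table for
all-smart standard-cartridge use implies per-item footprints of ≈0.117 kg
per cartridge and ≈0.68 kg per case (solving its pattern-1/2 cells
linearly reproduces all nine of its cells), which contradicts the stated
footprints of 0.080 and 1.035 kg — while the per-cartridge SCC table and
the environmental savings tables *are* consistent with 0.080 kg. The
package keeps the stated footprints as defaults (configurable), so its
environmental cohort-cost table differs from the published one; the
economic tables are unaffected.

## What the synthetic generator does and does not capture

The generator emulates unimodal single-breath profiles and the *relative*
variability structure of repeated inhalations. It does not model
oropharyngeal deposition, device aerosol physics, intra-day variation
beyond the two-attempt rule, adherence, dropout, behavioural regression or
acceptance — so passing tests demonstrate internal consistency of the
simulation and accounting chain, not clinical validity. Real flow profiles
would change the calibrated cv value but not the structure of the results.

## Numerical choices and degenerate inputs

Duplicate or non-increasing time points, negative flows or pressure drops,
non-positive resistance, out-of-range gains ([0, 100] %) and mismatched
slope/time lengths raise `ValueError` subclasses. Truncated-normal draws
use the inverse-CDF transform with boundary clipping to guard `ppf`
round-off; an empty truncation interval (gain already at cap) yields the
cap. Zero-SD distributions degenerate to their (clipped) means. Volume uses
`numpy.trapezoid`; the dense-quadrature oracle in the tests includes the
curve breakpoints so the piecewise-linear integral is exact.

## Problem sizes

Tests run the Monte Carlo at 2,000–8,000 runs per cohort for behavioural
checks and at the full 104,500 for the calibration check; the acceptance
script always uses 104,500 runs per model (seconds of runtime). The
calibration script defaults to 50,000 runs per evaluation, which resolves
the learned fraction to about ±0.4 percentage points per bisection step.

## Limitations

Learned fractions and gain trajectories inherit the unpublished variability
magnitudes through one calibrated constant; the lead-in-year mechanism,
while the only one we found that reproduces both reported fractions from a
single schedule, is an interpretation. End-of-life and waste-stream
impacts, production-scale effects, discounting and currency conversion are
out of scope, as are QALYs and any clinical-outcome differences between
smart and regular inhalers.
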