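# Methods

## Scale and classification

The severity scale is a single axis on [−4, +4]: −4…−1 increasing
bradykinesia (OFF), (−1, +1) the ON state, +1…+4 increasing dyskinesia
(DYS). The classifier assigns OFF for values ≤ −1 and DYS for values ≥ +1,
so both boundary values belong to the pathological states; the ON band is
open. Values outside [−4, +4] are rejected at ingestion rather than
clamped — real algorithmic output is bounded by construction, so an
out-of-range value indicates a corrupt file. Only the simulator clamps (its
noise can overshoot the scale).

All times are integer minutes. Clock times are floored to the minute on
ingestion and stored as minutes since the Unix epoch; the analysis is
minute-native and sub-minute precision is meaningless here. Gaps are absent
index entries, never NaNs, and nothing imputes them.

## Cycle extraction

A levodopa cycle is the severity window from `pre_minutes` before to
`post_minutes` after one logged intake (defaults 20 and 90 → 111 samples).
Completeness is strict: a single missing minute anywhere in the window
discards the event. Patients without at least one complete cycle are
excluded, and the inclusion table records the attrition (events seen,
cycles kept, minutes analyzed) so real-data users can report the same trail.

Deliberate choices where the procedure was underdetermined:

- The *t* = 0 value is the series sample at the event's floored minute; no
  interpolation.
- Overlapping windows from closely spaced doses each count independently;
  with 3-hour schedules overlap is rare, and dropping either member would
  need an arbitrary rule.
- The event log is taken as ground-truth intake times; scheduled versus
  actual intake is a labeling question outside the pipeline.
- Session boundaries are not barriers: a window is judged only on which
  minutes exist. Correspondingly, the simulator emits one series per
  patient spanning all simulated days, with `session_id` naming the
  recording block.

## Response statistics

Within each intake-state stratum, cycles are point-sampled at exact
multiples of 5 minutes (no within-bin averaging — each grid value is the
single minute sample). Per offset the summary reports n, mean,
SEM = sample SD (n−1 denominator)/√n (NaN for n = 1), median and
quartiles with the linear-interpolation convention of mainstream numeric
stacks. Baseline normalization subtracts the *t* = 0 value per cycle;
normalized values may range over [−8, +8] and are not clamped, and the
intake-state label classified on raw values is preserved. Count-table
percentages round half-away-from-zero to one decimal, matching how such
tables are conventionally printed.

The analysis grid spans the extraction window (−20…+90 min by default) and
both are configurable together.

## Synthetic cohort model

The generator emulates the phenomenology the analysis assumes, with the
simplest standard pharmacometric structure:

- **Plasma:** one-compartment oral model; each dose contributes a Bateman
  curve `D·ka/(ka−ke)·(e^(−ke·τ) − e^(−ka·τ))`, superposed linearly.
  Controlled-release doses scale ka by `cr_ka_factor` (default 0.4).
- **Effect site:** first-order equilibration `dCe/dt = ke0·(Cp − Ce)`,
  integrated by the exact exponential update for plasma interpolated
  linearly over each minute step. The piecewise-linear form is chosen over
  piecewise-constant because it introduces no artificial one-minute lag:
  Ce converges pointwise to Cp as ke0 → ∞, the correct fast-equilibration
  limit (the residual error scales as max|dCp/dt|/ke0).
- **Severity:** sigmoid-Emax response
  `baseline + span·Ce^h/(ec50^h + Ce^h)`, plus a 24-h sinusoid (default
  amplitude 0.15 scale units, minimum at 04:00) and stationary AR(1) noise
  (default innovation SD 0.3, lag-1 autocorrelation 0.8 → stationary SD
  0.5), clamped to [−4, +4]. Dyskinesia is overshoot of the same sigmoid
  past +1 — the scale is one-dimensional, so a separate dyskinesia process
  would add structure the analysis never sees.
- **Wear gaps:** a nightly half-open clock interval (default 23:00–06:00,
  420 min/day) plus Poisson-arriving daytime gaps with geometric lengths.
  A spec covering the whole day is rejected.

Default rates ka = 1.2–1.9/h, ke = 0.28–0.42/h, ke0 = 0.9–1.5/h are
calibration anchors placing the plasma peak at `ln(ka/ke)/(ka−ke)` ≈ 0.9–1.6 h
and the effect-site onset lag around 20 min — consistent with oral
levodopa's reported 0.5–2 h peak and 4–5 h decline. They are not fitted to
any dataset. ec50 is anchored per patient to the single-dose peak
effect-site concentration of the first scheduled dose (×0.8–1.2), so only
dose/ec50 ratios matter; `span` is then solved so the noise-free schedule
maximum lands at a phenotype-specific target peak severity:

| phenotype            | baseline (scale) | target peak (scale) | Hill    |
|----------------------|------------------|---------------------|---------|
| stable               | −0.9 … −0.4      | 0.2 … 0.7           | 1.8–2.8 |
| wearing_off          | −3.0 … −2.1      | −0.3 … 0.6          | 2.2–3.5 |
| brittle_fluctuator   | −3.2 … −2.4      | 1.8 … 3.2           | 2.8–4.5 |

Solving span from the target peak guarantees the phenotype geometry by
construction — stable peaks stay in the ON band, brittle peaks overshoot
into dyskinesia — instead of hoping a raw span draw lands there.

Randomness: one root seed; each patient's parameter and noise draws come
from a substream keyed on (seed, patient index), so growing a cohort never
reshuffles existing patients. `generate_cohort` is a pure function of its
config.

**What the generator does not emulate:** multi-compartment or
gastric-emptying kinetics, meal/protein interactions, adjunct COMT/MAO-B
effects, long-duration response and tolerance, tremor band structure, and
the inter-patient heterogeneity of real free-living data. Passing tests
therefore show that the pipeline implements its contracts and recovers the
qualitative stratified response shapes under the stated noise model — not
that any real cohort's magnitudes would be reproduced.

## Problem sizes

The direction-check scenarios (and `scripts/acceptance.py`) use cohorts of
50 single-phenotype patients, four 100 mg doses/day at 3-hour intervals
(08:00–17:00), 3 days, noise SD 0.3 with autocorrelation 0.8 — a few
hundred cycles per stratum, enough for stable mean curves while a full
test run and the acceptance script each finish in seconds. Unit fixtures
use hand-enumerable series of a few hundred minutes.

## Known limitations

- Short within-window gaps are never imputed; real deployments may want a
  tolerance for isolated missing minutes before discarding an event.
- The intake-state rule uses the single minute at *t* = 0; a noisy sample
  at exactly that minute can misclassify a cycle near a band boundary.
- The per-stratum SEM treats cycles as independent although cycles from one
  patient share parameters; no random-effects structure is modeled.
- The biphasic dyskinesia-stratum shape (initial dip, rebound after the new
  dose takes hold) emerges from prior-dose washout in the simulator; its
  depth is phenotype- and noise-dependent and should not be read as a
  clinical effect size.
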