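# levocycle

Medication-locked analysis of minute-resolution Parkinson motor-state
series from wrist-worn sensors.

People with advanced Parkinson's disease fluctuate between bradykinetic OFF
periods, a well-controlled ON state, and levodopa-induced dyskinesia. Modern
wearable algorithms summarize this on a single minute-by-minute severity
scale on [−4, +4]: −4…−1 is increasing bradykinesia (OFF), the open interval
(−1, +1) is ON, and +1…+4 is increasing dyskinesia (DYS). `levocycle` takes
such a severity series PD9(t) together with a medication log and answers the
clinical question *"what happens to motor severity after each levodopa
dose, depending on the state the patient was in when they took it?"* It is
aimed at movement-disorder researchers and methods developers working with
continuous motor-state monitoring.

## Method

For each logged intake at time *t* = 0:

- **Cycle extraction.** The window PD9(−20 min … +90 min) is extracted; only
  *complete* windows (all 111 minute samples present — no non-wear gap)
  count as levodopa cycles, and patients without at least one complete
  cycle are excluded.
- **State at intake.** Each cycle is classified by its value at *t* = 0:
  OFF if PD9 ≤ −1, DYS if PD9 ≥ +1, ON otherwise.
- **Stratified response curves.** Within each stratum (ALL/OFF/ON/DYS),
  point samples on a 5-minute grid are summarized per offset as *n*, mean,
  SEM = s/√n, median and quartiles — for the raw severity and for the change
  from baseline PD9(t) − PD9(0).

Because the sensor data such analyses run on are not publicly deposited, the
package ships a first-class synthetic generator: a one-compartment oral PK
model (Bateman curve, plasma peak 0.5–2 h post-dose), a first-order effect
compartment for the ~20 min onset lag, a sigmoid-Emax (Hill) severity
response over an OFF baseline with dyskinesia as overshoot past +1, AR(1)
noise, circadian modulation, and overnight/daytime non-wear gaps. Three
phenotypes (stable / wearing-off / brittle fluctuator) set where the
response lands on the scale.

## Worked example

```python
from levocycle import (
    CohortConfig, NoiseSpec, MotorState, generate_cohort,
    filter_included_patients, stratify, summarize, state_count_table,
)
from levocycle.synthetic import DoseSpec

config = CohortConfig(
    n_patients=20,
    phenotype_mix={"stable": 0.3, "wearing_off": 0.45, "brittle_fluctuator": 0.25},
    dose_schedule=tuple(DoseSpec(c) for c in ("08:00", "11:00", "14:00", "17:00")),
    n_days=2,
    noise=NoiseSpec(sigma=0.3, phi=0.8),
    seed=42,
)
cohort = generate_cohort(config)
included, accounting = filter_included_patients([(s, e) for s, e, _ in cohort])
cycles = [c for _, cyc in included for c in cyc]
print(f"{len(included)} of {len(cohort)} patients included, {len(cycles)} complete cycles")

counts = state_count_table(cycles)
for state in MotorState:
    print(f"  {state}: {counts.counts[state]} ({counts.percentages[state]}%)")

off = stratify(cycles)[MotorState.OFF]
curve = summarize(off, stratum="OFF", normalized=True).rows["mean"]
print(f"OFF-stratum mean change from baseline at +70 min: {curve.loc[70]:+.2f}")
```

prints

```
20 of 20 patients included, 160 complete cycles
  OFF: 37 (23.1%)
  ON: 107 (66.9%)
  DYS: 16 (10.0%)
OFF-stratum mean change from baseline at +70 min: +1.20
```

Every scheduled dose with a fully recorded window became a cycle (the
nightly 23:00–06:00 non-wear gap breaks none of the daytime windows here);
most intakes caught the patient ON, and doses taken in the OFF state
produced a mean symptom relief of about +1.2 scale units by 70 minutes —
the severity rises out of the OFF band toward ON.

The same pipeline runs from the shell on delimited-text inputs or a
simulation block in a YAML config:

```bash
levocycle simulate --config run.yaml --seed 1
levocycle analyze  --config run.yaml --seed 1 --out results/
```

`analyze` writes the cycle table, the state-count table, raw and normalized
response summaries, and the standard figures (daily severity graph with the
ON band shaded, single-cycle view, per-stratum boxplots and mean ± SEM
panels). Exit code 3 flags inputs with no complete cycle.

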