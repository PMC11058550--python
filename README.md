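# myotrain

Device logic for ambulatory **upper-airway muscle training** (myofunctional
therapy) in obstructive sleep apnea/hypopnea syndrome (OSAHS), re-implemented
as a testable Python library. A custom mouthpiece senses lip and tongue cavity
pressure; participants train at home with pressure-biofeedback tasks and games,
6 sessions a week for 4 weeks, ~35 minutes per session. The package covers the
whole software stack of such a device plus the analytics used to evaluate it:

* **signal_core** — uniformly sampled `PressureTrace`s (kPa, 50 Hz default) and
  the windowed primitives everything else reduces to (window means, fraction of
  time in a band / above a threshold).
* **calibration** — zero-offset measurement (with the mouthpiece's thermal
  baseline drift in mind) and the 3-attempt maximal-pressure procedure with its
  7.5 % consistency rule, which establishes Pmax.
* **tasks** — the tongue/lip tracking task (10 cycles; 8 s rest, 3 s target at
  3–5 % of Pmax, scored over the final 1.5 s of each target) and the breathing
  task (7 × 16 s breaths while holding ≥ 4 % of Pmax).
* **games** — the paddle, circle, missile and wall games as seeded,
  fixed-timestep, bit-replayable state machines (logged, never analysed).
* **session** — the full session state machine (calibrations → warm-up game →
  4 rounds of breathing/lip/tongue tasks + games) and JSON session logs that
  round-trip exactly.
* **simulate** — synthetic users (learning curves, reaction latency, tracking
  noise, thermal drift, imperfect adherence, dropout) and whole cohorts with
  programmable clinical covariates.
* **analytics** — compliance (completed/24), first-day vs last-day success
  summaries with the ±1.96 SD dispersion band, Spearman correlations with
  exact permutation p-values (all n! orderings for n ≤ 8), and a paired
  sign-flip permutation test for pre/post comparisons.

## Core definitions

For a trace sampled at rate *f*ₛ, the tracking-task score is

    score = (100 / n_cycles) · Σₖ  #{samples in scored window k with
             0.03·Pmax ≤ p ≤ 0.05·Pmax} / #{samples in scored window k}

where Pmax is the mean of three maximal-effort peaks accepted only when
max|peakᵢ − mean| / mean ≤ 0.075. The breathing score is the fraction of the
whole 112 s task with p ≥ 0.04·Pmax. Compliance is completed sessions / 24.
Associations use Spearman's Rₛ (midranks) with p from exact enumeration of
permutations.

## Worked example

`python examples/06_clinical_tables.py` recomputes the evaluation-study group
numbers from the bundled per-participant tables:

```
overall compliance: 175/192 = 91% (worst participant 75%)
tongue success: 66% (SD 18) -> 85% (SD 17)
lip success: 78% (SD 18) -> 87% (SD 16)
AHI: 20.7 -> 17.7 events/h (paired sign-flip permutation p = 0.086)
```

91 % is the pooled compliance of the 8 completers; tongue success rises from
66 % on the first training day to 85 % on the last; mean apnea-hypopnea index
moves from 20.7 to 17.7 events/h (not significant under the sign-flip test).
`python examples/03_run_a_full_session.py` runs one simulated ~34-minute
session end to end and prints its calibrations, 12 task scores and game high
scores.

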