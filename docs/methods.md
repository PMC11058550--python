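# Methods

## The device model

Two gauge-pressure channels (lip and tongue cavities of a silicone
mouthpiece) are sampled uniformly. The implementation treats a trace as a
plain array at a fixed sampling rate; no transducer or ADC modelling is
attempted. Pressures are in kPa and the default rate is **50 Hz** — the
hardware's true rate is not part of this artifact's contract, and 50 Hz was
chosen once so that the 1.5 s scored window of a tracking cycle contains 75
samples (a one-sample edge effect moves a cycle fraction by < 1.5 %).

Windowing conventions, fixed throughout:

* time windows are half-open `[start, end)` so adjacent cycle windows never
  double-count a sample;
* band membership is closed `[lo, hi]` — a pressure on the box edge counts;
* all fractions are computed sample-wise, never by interpolating crossing
  times, because that is what a sampled digital device measures.

## Calibration

**Zero calibration.** The mouthpiece warms in the mouth, and the trapped-air
baseline drifts like a first-order system, `b(t) = b_inf · (1 − e^(−t/τ))`
with τ ≈ 20 s, settling within about a minute. The offset is the mean
pressure over the final 2 s of a relaxed epoch. A session therefore zeroes
once at insertion, plays a 2-minute warm-up game, and re-zeroes; the
post-warm-up record is authoritative, and a fresh zero calibration precedes
every training round (a per-task variant is a config switch,
`SessionConfig.zero_per_task`).

**Maximal pressure.** Three consecutive maximal-effort attempts; the round is
accepted iff `max_i |peak_i − mean| / mean ≤ 0.075`, in which case the mean
becomes Pmax. Interpretation choices: "deviation" is read as the **maximum**
absolute deviation (strictest reading; mean-absolute-deviation is available
via `CalibrationPolicy(deviation="mean")`); the boundary value 7.5 % is
accepted, since a repeat is demanded only when the deviation is *greater*;
on repeat all three attempts are redone. The loop caps at 5 rounds and then
returns an *unaccepted* result rather than raising — the session engine
decides what to do with it. Within an attempt the per-segment peak is used
(whether the original device took a peak or an average before "OK" is not
knowable from the outside; the peak is the natural reading for a maximal
effort).

If Pmax is never accepted, the session continues on a fallback reference
(the last round's mean if positive, else a nominal 10 kPa) so that task
scores are still logged, but the session is flagged not completed with a
reason. This keeps a useless calibration from silently producing
plausible-looking scores while still recording what the participant did.

## Tasks

Tracking task: `n_cycles = 10` cycles of `rest = 8 s` then `target = 3 s`
with the band at 3–5 % of Pmax; the first `react = 1.5 s` of the target
phase is a grace period and the cycle fraction is the in-band fraction over
the remaining 1.5 s. The task score is 100 × the arithmetic mean of cycle
fractions — identical to pooling samples, since scored windows are equal
length. The band is a fixed target (not a per-cycle random level), rest
behaviour is logged (mean rest pressure per cycle) but never scored or
penalised, and band edges are inclusive.

Breathing task: 7 breaths × (8 s inhale + 8 s exhale) = 112 s while holding
lip pressure ≥ 4 % of Pmax; the score is the fraction of the *whole* task
above threshold. The on-screen breathing guide is display-only and does not
enter scoring.

## Games

The four games (paddle, circle, missile, wall) are fixed-timestep
(`dt = 1/fs`) state machines on a 1×1 field, deterministic given
(rules, seed, input stream) — the property the replay tests exercise.
Mechanics follow the device's descriptions; every numeric constant is an
invented configuration default, not a claim: initial speed 0.5 field/s,
×1.1 per success, paddle length 0.2, circle radius 0.15 shrinking ×0.9 to a
0.05 floor with a 3 s dwell, 30 s countdown and +7 s per success,
press-release hysteresis at 2 %/1 % of Pmax, wall-hole step 0.1, 6 missile
colours, and 10 % of Pmax mapping to full field deflection. A missile
colour miss resets the current score (the source material is silent; this
matches the paddle and wall counters). Game scores are archived but
excluded from all success analytics.

## Session

Step order: zero cal → warm-up game (120 s, paddle) → zero cal → max cal
tongue → max cal lip → 4 × [zero cal, breathing, lip task, tongue task,
game], with game variants rotating through all four in a seeded order. At
defaults the scheduled duration is 33.8 min, inside the expected ~35-minute
envelope. Every task in a session is scored against that session's accepted
Pmax. A session counts as *completed* for compliance iff all 12 tasks
produced scores and both calibrations were accepted. Logs are
schema-versioned JSON, one document per participant, with exact round-trip
(`read(write(x)) == x` field for field).

## The synthetic-user model

The simulator provides the statistical structure the analytics assume; its
defaults are the study conditions.

* **Maximal pressures**: tongue 40 kPa, lip 20 kPa — typical healthy-adult
  values on comparable tongue/lip manometry.
* **Skill** (per-sample in-band probability) learns exponentially:
  `skill(day) = s_inf − (s_inf − s_0)·e^(−day/κ)` with defaults
  `s_0 = 0.66`, `s_inf = 0.87`, `κ = 10` days, chosen to emulate the
  observed ≈66 % → ≈85 % group trajectory over 28 days.
* **Trace generation**: during a target the mean pressure approaches the
  band centre first-order (τ = 0.3 s) after a 0.5 s reaction latency, and is
  *exactly* the band centre once the scored part of the cycle begins. White
  Gaussian noise of SD σ is added, with σ inverted from skill via
  `P(in band) = 2·Φ(h/σ) − 1  ⇒  σ = h / Φ⁻¹((1+skill)/2)` for band
  half-width h. This makes the per-sample in-band probability in scored
  windows equal skill(day) exactly, which is what the parameter-recovery
  tests check (a skill-0.7 user scores 70 ± 3 over 200 cycles). For the
  breathing task the mean is set to `threshold + σ₀·Φ⁻¹(skill)` at fixed
  σ₀ = 1 % of Pmax, so the per-sample above-threshold probability is skill.
* **Thermal drift** is added to every raw trace; the session engine removes
  it through its own measured zero offsets, and a property test confirms a
  pre-warm-up zero calibration mis-estimates the steady-state baseline more
  than a post-warm-up one whenever `b_inf > 0`.
* **Adherence**: each prescribed day (6/week) is attended with probability
  `adherence` (default 0.92); dropout is a geometric daily hazard, default
  0.008/day ⇒ ≈20 % dropout over 4 weeks, motivated by 2 of 10 enrollees
  leaving within days. `simulate_attendance` exposes exactly this process so
  compliance properties can be checked without paying for full-session
  simulation; `simulate_participant` runs every attended day through the
  real session engine.
* **Covariates**: pre-AHI is log-normal (mean 20.7, SD 17.8 events/h);
  the change in supine AHI is tied to each participant's lip-score
  improvement through a Gaussian copula on ranks with latent correlation
  `2·sin(π·ρ_s/6)`, so the programmed Spearman target ρ_s (default −0.76)
  is recovered in expectation — and exactly at ρ_s = ±1, where the copula
  degenerates to a deterministic monotone map. Post values are kept
  non-negative by a *common* shift rather than per-participant clipping,
  which would tie the changes and destroy the programmed rank association.

What the simulator does **not** model: respiratory waveforms, airway
mechanics, fatigue within a session, transducer nonlinearity, or any
causal link between training and AHI — the covariate association is
programmed, not emergent. Passing tests therefore demonstrate that the
engine and analytics measure what they claim on signals with the assumed
structure, not that the therapy works.

## Analytics

Compliance is completed/prescribed per participant and pooled overall
(these coincide as a mean when all denominators are 24). Success summaries
take each participant's first and last *completed* session (the resolution
chosen for partial attendance), average the session's task scores per kind,
and report cross-participant mean and SD (ddof = 1), with the "96 % CI"
reproduced exactly as the evaluation reported it — mean ± 1.96 SD of the
raw values, a dispersion band rather than a standard-error interval; the
`SuccessSummary.dispersion_band` flag marks this. Report percentages round
half-up to integers (AHI to 1 decimal), matching the printed tables.

Spearman's Rₛ uses midranks (scipy's implementation; the tied-pair case is
pinned to a hand-computed oracle). Permutation p-values enumerate all n!
permutations of one vector for n ≤ 8 (8! = 40 320) and fall back to seeded
Monte-Carlo (≥10⁴ draws, identity included) above; p is the proportion of
permutations with |Rₛ| at least the observed (to a 1e−12 tolerance), hence
deterministic and ≥ 1/n! in exact mode. Pre/post comparisons use a
two-sided sign-flip permutation test on the mean paired difference, exact
to 2²⁰ flips — a declared substitute for random-intercept mixed-model
inference, not a replication of its P values.

## Problem sizes and tolerances used in the checks

The scoring-oracle equivalence suite compares the 50 Hz scorer with an
independent dense per-sample loop at 500 Hz on 100 random band-limited
traces (60 tracking + 40 breathing), at a 2-percentage-point tolerance
covering the residual discretisation difference. Parameter recovery uses
200 simulated cycles (binomial SE ≈ 0.4 points, asserted at ±3) and 50
simulated participants for adherence (±1.96·binomial SE). End-to-end runs
use an 8-participant, 4-week cohort with full sessions. The acceptance
script repeats these sizes and finishes in well under a minute.

## Known limitations

* The breathing-task group trajectory (≈86 % → 96 %) and the published
  supine-AHI correlation (Rₛ = −0.76) rest on per-participant values that
  were never printed; they are covered by simulator-driven property checks
  (programmed associations are recovered, exactly at ρ = ±1), not
  reproduced from data.
* Mixed-model P values are out of scope by design; the sign-flip test is
  the package's own inference and will not match them numerically.
* Game physics constants are plausible inventions; only the mechanics and
  the scoring/timer rules are grounded.
* The 66 %/85 % success figures are reproduced as participant means of the
  printed per-participant rates; the original count-style denominators
  (x/320) are not derivable from the published material.
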