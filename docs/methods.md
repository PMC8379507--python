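# Methods

This note records how `cpraid` defines, computes and tests its quantities,
and which choices were genuinely open.

## Time model and the event log

All timestamps are seconds from scenario start; t = 0 is scenario start, not
team arrival, and all "time to" metrics subtract `arrival_time` explicitly.
Intervals are half-open: a compression segment [10, 40) contributes 30 s of
flow.  The cardiac-arrest interval used as the no-flow denominator runs from
`arrival_time` to min(ROSC, scenario end): the team cannot compress before it
reaches the patient, and anchoring at arrival matches the arrival-anchored
time-to-first definitions.  Anchoring at collapse instead would be equally
defensible for a witnessed arrest with a known collapse time; the choice is
isolated in `metrics.arrest_interval`.

Defibrillations, drug doses and compressor changes are point events; rhythm
checks are intervals (start/end), and the check *start* times define the
cycle, because that is when compressions pause for analysis.  Compression
start/stop events must strictly alternate; an unterminated final segment is
closed at scenario end.  `validate_log` is total — it reports every broken
rule (ordering, bounds, alternation, pairing, arrival precedence) rather than
raising on the first.

## The twelve variables

* **No-flow fraction** = 100 × (arrest duration − compression time within the
  arrest interval) / arrest duration.
* **Depth / rate**: duration-weighted means over the simulator's per-period
  samples; absent when the export failed.
* **Times to first rhythm analysis / first shock**: first event minus
  arrival; a team that never shocks has no time-to-first-shock.
* **Cycle deviations** (rhythm checks, compressor changes): the first
  interval is anchored at arrival, subsequent intervals run between
  consecutive events; each contributes max(0, interval − 120 s) and the
  variable is the mean.  Early actions are never penalized — conformance is
  one-sided.  Anchoring the first compressor-change interval at arrival
  (rather than at the first change) was an open choice; arrival keeps the
  two cycle variables symmetric.
* **Adrenaline deviation**: the first dose is exempt; each inter-dose
  interval Δ contributes 180 − Δ if too early, Δ − 300 if too late, else 0.
* **Expected counts**: ⌊scenario length / 120⌋ rhythm checks and compressor
  changes, ⌊scenario length / 240⌋ adrenaline doses (240 s = redosing-window
  midpoint).  These floor rules are configuration (`AlgorithmTargets`), not
  guideline constants: a different counting convention drops in without
  touching code, and the scoring shortfall rule (meet → 2, one short → 1,
  two+ short → 0) lives in the rubric file for the same reason.
* **Amiodarone**: classified none / given / given after the third shock and
  before the fourth (the guideline indication in refractory VF).

## Rubric and aggregate score

Band edges come from the 15 % margin rule: score 2 up to the guideline
threshold *T*, score 1 up to *T*(1+margin), score 0 beyond — 120 s → 138 s
for the two time-to-first variables; deviation variables use margin
fractions of the cycle, 0.15·120 = 18 s and 0.30·120 = 36 s.  Three rubric
rows deviate from the plain rule and are encoded literally in
`data/rubric.yaml`:

* no-flow fraction: ≤ 15 → 2, ≤ 20 → 1, > 20 → 0 (the published band, which
  overrides 15 × 1.15 = 17.25);
* adrenaline deviation: 2 iff the mean deviation is exactly 0, else 0 — no
  middle band;
* depth and rate: 2 inside the guideline range (5–6 cm, 100–120 min⁻¹), else
  0, no middle band.  The published rubric prints "5–6" for both depth and
  rate; for rate that is a typesetting slip, and the implemented 100–120
  min⁻¹ range follows guideline wording and is consistent with both arms'
  observed means (119/121 min⁻¹).

A team that never defibrillated scores 0 (worst band) on time to first
shock rather than missing, so it stays in the cohort.  The CPR performance
score is the arithmetic mean of non-missing scores; only the depth+rate
missingness pattern is accepted (10-variable mean), anything beyond that is
an error rather than a silent skip.

`expected_cohort_score` is the consistency identity tying a score-share
table to group means: per variable E = Σ k·p(k); teams with compression data
average 12 expectations, teams without average 10; the group expectation is
the team-weighted mean.  With the packaged calibration table this gives
1.467 vs 1.239 — matching the published 1.47 / 1.24 and their 0.23
difference.

## Cognitive-aid engine

A pure state machine: `advance(state, dt)` moves time, `press(state,
button, t)` documents an action, both returning new frozen states, so any
trace replays identically (no wall clock).  Thresholds (configurable in
`AidConfig`): rhythm-check alert turns *prepare* at 100 s and *due* at
120 s, boundary-inclusive; the compressor-change icon follows the 100 s
alert; the adrenaline timer turns *consider* at 180 s — the opening of the
3–5-minute redosing window; the app itself does not print this threshold, so
it is an explicit, configurable guess.  All alerts are recomputed from the
timers except the amiodarone prompt, which latches from every third
defibrillation until amiodarone is documented (when the icon clears is not
specified; latching is the conservative reading).

## Statistics

* **ICC(A,1)** from two-way ANOVA mean squares,
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n), with the McGraw–Wong
  F-based 95 % CI; degenerate tables (zero error and rater variance) return
  a point interval.  The estimate and CI agree with pingouin's ICC(A,1) row
  to 1e-9 on fixtures; pingouin is used only as a cross-check in tests.
* **Normality gate**: Lilliefors-corrected KS by default (parameters are
  estimated from the sample); the uncorrected KS against N(x̄, s) is
  available by flag.  Constant samples fail the gate by definition.
* **t path**: pooled-variance t-test, Cohen's d on the pooled SD, 95 % CI of
  the mean difference from the pooled SE.
* **Mann–Whitney path**: exact p for both-group n ≤ 8 without ties, normal
  approximation with tie correction otherwise.  Rank-biserial r uses
  r = 1 − 2U/(n₁n₂) with U counting pairs where the second group exceeds the
  first (ties half-weighted), making r positive when the first group is
  stochastically larger; this equals the dominance difference
  (#(a>b) − #(a<b))/(n₁n₂), verified exhaustively for group sizes ≤ 5.
* **Fisher exact**: two-sided by summing hypergeometric probabilities no
  larger than the observed table's (the common convention; conventions
  differ, so it is stated).
* **Sample size**: per-group n = ⌈2(z₁₋α/₂ + z_power)²/d²⌉, the normal
  approximation.  Power is always an explicit parameter: at d = 0.8 and
  α = 0.05 the helper returns 33/group at power 0.9 and 25/group at 0.8.
* **Raw NASA-TLX**: unweighted mean of the six subscales.

## Synthetic cohorts

Two fidelity levels, both fully seeded (`numpy.random.SeedSequence`
throughout; per-team seeds are spawned from the master seed).

**Calibrated score sampling** draws each variable's 0/1/2 score
independently from a per-group share table (`data/calibration.yaml`, the
published cohort's score shares and raw summaries — calibration input, not
ground truth), with a configured number of teams per cohort missing
depth/rate.  Cross-variable correlation is deliberately not modeled: the
sampler is a statistical twin of the marginal score distributions, which is
exactly what the expected-score identity and its stochastic check need.
Its grand mean over many cohorts converges on the calibration's implied
group mean (≈ 1.467 for the aided arm) but its between-team score *variance*
understates reality, where good teams are good across variables.

**Mechanistic simulation** generates full event logs of a persistent-VF
arrest.  Defaults (in `aided_config` / `unaided_config`) are calibration
choices set once so that 100-team cohort summaries land near the published
group values, since no timing distributions for team behavior are published:

| quantity | aided | unaided | target (published M) |
|---|---|---|---|
| scenario length s | N(943, 110) | N(902, 100) | 943 / 902 medians |
| first rhythm check s after arrival | N(74, 30) | N(98, 50) | 74 / 98 |
| cycle delay s (added to 120 s) | N(12, 10)⁺ | N(27, 31)⁺ | dev 12 / 31 |
| first-shock lag after first check s | N(37, 18) | N(37, 18) | 111 / 135 |
| adrenaline interval s | N(270, 60) | N(300, 110) | dev 17 / 51 |
| hands-off pause per check s | N(15, 4) | N(18, 6) | no-flow 13.3 / 14.1 % |
| change skip probability | 0.12 | 0.22 | dev 29 / 59 |
| amiodarone compliance | 0.81 | 0.74 | score-2 shares |
| depth cm / rate min⁻¹ | N(4.6, 1), N(121, 7) | N(4.0, 1), N(119, 12) | table means |
| P(missing compression export) | 5/32 | 9/31 | footnote counts |

⁺ one-sided: delays are normals truncated at 0, matching the max(0, ·)
deviation definition; the recovery tests compare against the truncated mean
E[max(0, X)] = μΦ(μ/σ) + σφ(μ/σ).

Aided teams' documentation presses are replayed through the aid engine,
yielding interaction logs at ≈ 1.9 presses/min with the default 0.75/min
non-documentation press rate.  The simulator models no physiology (VF
persists unless a ROSC time is configured), no ECG misinterpretation, no
within-team learning, and independent teams; passing tests therefore
demonstrate the *pipeline's* correctness and the generator's internal
consistency, not fidelity of any particular team-behavior model.

## Numerical and testing choices

* The brute-force no-flow oracle sweeps 10 ms bins; its own discretization
  error (half a bin per segment boundary) stays well below the 0.2
  percentage-point comparison tolerance even on short, fragmented logs.
* Band-edge tests probe exactness one representational step (`nextafter`)
  past each threshold.
* Problem sizes in the tests — 500 random logs for oracle equivalence, 200
  teams for parameter recovery, 100 seeded replications of 32 + 31 teams for
  the directionality check, 1,000 cohorts for the sampling check — were
  chosen so the statistical assertions have comfortable margins while the
  whole suite stays inexpensive.
* Events sharing a timestamp sort by kind name for a stable serialization;
  scenario lengths are floored at 400 s so every simulated scenario contains
  at least two full cycles.

## Known limitations

* The expected-count floor rule and its shortfall scoring stand in for an
  action-count scoring table that is not published in full; both are
  configuration and flagged as such.
* The mechanistic generator's timing distributions are calibrated guesses;
  only their cohort-level summaries, not their shapes, are anchored to data.
* The rank-biserial/U sign convention, the Fisher two-sided convention and
  the Lilliefors default are stated choices; alternatives exist in the
  literature and flags expose the uncorrected KS variant.
* Exclusions are analyst flags in the manifest, never automated detection —
  the real-world exclusion reasons (off-script scenarios, hardware failure)
  are judgment calls.
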