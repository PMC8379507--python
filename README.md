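# cpraid

Guideline-conformance analysis of simulated cardiopulmonary resuscitations.

`cpraid` is for researchers in resuscitation human factors who assess how
closely emergency teams follow the advanced-life-support (ALS) algorithm in
high-fidelity simulation — in particular when evaluating cognitive aids such
as timer/alert apps.  It turns timestamped scenario event logs (the product
of video coding or simulator exports) into twelve objective performance
variables, scores them on a 0/1/2 rubric, aggregates a per-team CPR
performance score, and compares study arms with the appropriate tests and
effect sizes.  A deterministic re-implementation of a cognitive-aid app's
timer logic and a seeded synthetic cohort generator make every stage of the
pipeline runnable and testable without any study data.

## The score at the core

For each team, twelve variables are measured against the ALS algorithm for a
shockable rhythm:

* **no-flow fraction** — no-flow time / total arrest time (arrest runs from
  team arrival to ROSC or scenario end), in %;
* **mean compression depth (cm) and rate (min⁻¹)** — duration-weighted means
  of the simulator's per-period export, when it recorded;
* **time to first rhythm analysis and to first shock** — seconds from
  arrival;
* **cycle deviations** — rhythm checks and compressor changes are due every
  *T* = 120 s; each interval contributes max(0, interval − *T*), and the team's
  deviation is the mean.  Adrenaline redosing has a two-sided window
  [180 s, 300 s]: intervals below it count the shortfall, above it the excess;
* **expected action counts** — ⌊length/120⌋ rhythm checks and compressor
  changes, ⌊length/240⌋ adrenaline doses for a scenario of that length;
* **amiodarone timing** — none / given / given after the third shock.

Each variable maps to 0, 1 or 2 points.  Smaller-is-better time variables use
a 15 % margin band: score 2 up to the threshold *T*, score 1 up to
*T*(1 + 0.15) (so 120 s → 138 s), score 0 beyond; deviation variables use
margin fractions of the cycle (≤ 18 s → 2, ≤ 36 s → 1).  The **CPR
performance score** is the mean of the non-missing variable scores (0–2
scale); teams whose compression export failed are scored on the remaining
ten variables.

Group comparisons follow a Kolmogorov–Smirnov normality gate: independent
t-test with pooled-SD Cohen's *d* and a 95 % CI of the mean difference when
both samples pass, Mann–Whitney *U* with rank-biserial
*r* = 1 − 2*U*/(*n₁n₂*) otherwise; 2×2 frequencies use Fisher's exact test.
Double-coding reliability uses ICC(A,1) — two-way model, absolute agreement,
single rater — from ANOVA mean squares with McGraw–Wong F-based confidence
bounds.  Subjective workload uses the raw NASA-TLX (unweighted mean of the
six subscales).

## Worked example

```python
from cpraid.metrics import compute_all
from cpraid.scoring import score_team
from cpraid.synthetic import aided_config, simulate_team_log

log, series, presses = simulate_team_log(aided_config(), team_seed=7, team_id="demo")
pv = compute_all(log, series)
card = score_team(pv)
print(f"no-flow {pv.no_flow_fraction:.1f}%  first shock {pv.t_first_shock:.0f}s  "
      f"rhythm deviation {pv.dev_rhythm:.1f}s")
print(f"CPR performance score {card.cpr_score:.2f} over {card.n_scored} variables")
```

prints

```
no-flow 10.9%  first shock 101s  rhythm deviation 9.8s
CPR performance score 1.17 over 12 variables
```

— this aided team keeps hands-off time inside the ≤ 15 % band (score 2),
shocks within the 120 s threshold (score 2) and holds the rhythm-check cycle
(mean delay 9.8 s ≤ 18 s, score 2), but loses points on compression depth
and rate, missed compressor changes and off-window adrenaline spacing,
averaging 1.17 across the twelve variables.

The `analysis/` scripts run the study end to end on a synthetic cohort:
`01_simulate_cohort.py` (67 teams, 4 analyst exclusions → 32 + 31 analysed),
`02_score_teams.py` (metrics, scorecards, score-share summary),
`03_group_comparison.py` (arm contrast plus the score-share consistency
computation), `04_reliability_and_app_use.py` (double-coding ICC and app
interactions per minute).  Tables land under `results/`; the raw cohort under
`scratch/`.

There is also a small CLI mirroring those steps:
`cpraid simulate|score|analyze|report|reliability --help`.

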