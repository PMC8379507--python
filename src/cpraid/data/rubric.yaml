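# Scoring rubric: 0/1/2 points per performance variable.
#
# Band construction for "smaller is better" time variables follows the 15%
# margin rule: score 2 up to the guideline threshold, score 1 up to
# threshold * (1 + margin), score 0 beyond.  Deviation variables use margin
# fractions of the 2-minute cycle: 0.15*120 = 18 s and 0.30*120 = 36 s.
# The adrenaline-deviation rubric has no middle band (score 2 iff the mean
# deviation is exactly zero).  Compression depth/rate score 2 inside the
# guideline range and 0 otherwise, also with no middle band; depth 5-6 cm,
# rate 100-120 /min.
#
# Count variables (expected number of rhythm checks, compressor changes,
# adrenaline doses given the scenario length) are scored by shortfall from
# the expectation: meet it -> 2, one short -> 1, two or more short -> 0.
# This shortfall rule is configuration, not a guideline constant, and can be
# replaced here without touching code.
margin: 0.15
variables:
  no_flow_fraction:
    kind: lower_better
    score2_max: 15.0
    score1_max: 20.0
  avg_depth:
    kind: range
    score2_range: [5.0, 6.0]
    missing_allowed: true
  avg_rate:
    kind: range
    score2_range: [100.0, 120.0]
    missing_allowed: true
  t_first_rhythm:
    kind: lower_better
    score2_max: 120.0
    score1_max: 138.0
  t_first_shock:
    kind: lower_better
    score2_max: 120.0
    score1_max: 138.0
    absent_score: 0          # a team that never shocked gets the worst band
  n_compressor_changes:
    kind: count
  dev_compressor_change:
    kind: lower_better
    score2_max: 18.0
    score1_max: 36.0
  n_adrenaline:
    kind: count
  dev_adrenaline:
    kind: lower_better
    score2_max: 0.0
    score1_max: 0.0          # no middle band: any nonzero deviation scores 0
  n_rhythm_checks:
    kind: count
  dev_rhythm:
    kind: lower_better
    score2_max: 18.0
    score1_max: 36.0
  amiodarone:
    kind: categorical
    mapping:
      NONE: 0
      GIVEN: 1
      AFTER_THIRD_SHOCK: 2
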