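# Calibration table for the score-sampling generator: per-group, per-variable
# score proportions (percent scoring 0 / 1 / 2) and raw-value mean/SD where the
# variable is continuous.  These are the published cohort summaries the
# statistical twin reproduces — calibration inputs, not ground truth about any
# new cohort.  missing_depth_rate counts teams whose simulator compression
# export failed; those teams are scored on the remaining ten variables.
groups:
  CA_APP:
    n_teams: 32
    missing_depth_rate: 5
    variables:
      no_flow_fraction:        {p: [9.4, 12.5, 78.1],  mean: 13.28, sd: 4.09}
      avg_depth:               {p: [53.8, 0.0, 46.2],  mean: 4.6,   sd: 1.0}
      avg_rate:                {p: [50.0, 0.0, 50.0],  mean: 121.0, sd: 7.0}
      t_first_rhythm:          {p: [6.3, 0.0, 93.7],   mean: 74.0,  sd: 30.0}
      t_first_shock:           {p: [18.8, 9.3, 71.9],  mean: 111.0, sd: 67.0}
      n_compressor_changes:    {p: [12.5, 46.9, 40.6]}
      dev_compressor_change:   {p: [31.3, 18.7, 50.0], mean: 29.0,  sd: 28.0}
      n_adrenaline:            {p: [3.1, 15.6, 81.3]}
      dev_adrenaline:          {p: [59.4, 0.0, 40.6],  mean: 17.0,  sd: 23.0}
      n_rhythm_checks:         {p: [0.0, 3.1, 96.9]}
      dev_rhythm:              {p: [6.3, 12.5, 81.3],  mean: 12.0,  sd: 11.0}
      amiodarone:              {p: [18.8, 0.0, 81.3]}
  NO_APP:
    n_teams: 31
    missing_depth_rate: 9
    variables:
      no_flow_fraction:        {p: [9.7, 25.8, 64.5],  mean: 14.06, sd: 4.40}
      avg_depth:               {p: [72.7, 0.0, 27.3],  mean: 4.0,   sd: 1.0}
      avg_rate:                {p: [31.8, 0.0, 68.2],  mean: 119.0, sd: 12.0}
      t_first_rhythm:          {p: [16.1, 3.3, 80.6],  mean: 98.0,  sd: 53.0}
      t_first_shock:           {p: [25.8, 9.7, 64.5],  mean: 135.0, sd: 82.0}
      n_compressor_changes:    {p: [38.7, 41.9, 19.4]}
      dev_compressor_change:   {p: [54.8, 22.6, 22.6], mean: 59.0,  sd: 68.0}
      n_adrenaline:            {p: [3.2, 9.7, 87.1]}
      dev_adrenaline:          {p: [74.2, 0.0, 25.8],  mean: 51.0,  sd: 70.0}
      n_rhythm_checks:         {p: [9.7, 9.7, 80.6]}
      dev_rhythm:              {p: [19.4, 45.2, 35.5], mean: 31.0,  sd: 31.0}
      amiodarone:              {p: [25.8, 0.0, 74.2]}
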