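#!/usr/bin/env python
"""Group comparison and score-share consistency analysis.

Two parts:

1. From the simulated cohort's comparison table (written by
   02_score_teams.py): report the CPR performance score contrast between the
   aided and unaided arms, with the test the normality gate chose and its
   effect size.

2. Independent of the simulation: the published per-variable score shares
   imply expected group means (Σ k·p(k) per variable; 12-variable mean for
   teams with compression data, 10-variable mean for those without).  This
   consistency computation — plus the a priori sample-size helper — goes to
   results/expected_scores.json.
"""

import json
from pathlib import Path

import pandas as pd

from cpraid.event_model import Group
from cpraid.scoring import expected_cohort_score
from cpraid.stats import sample_size_two_group
from cpraid.synthetic import table2_calibration

OUT = Path("results")


def main() -> None:
    comp = pd.read_csv(OUT / "comparisons.csv")
    row = comp[comp.variable == "cpr_score"].iloc[0]
    print(
        f"simulated cohort, CPR score: {row.test}, p = {row.p_value:.4f}, "
        f"{row.effect_name} = {row.effect_size:.2f}"
    )

    cal = table2_calibration()
    ca = expected_cohort_score(cal.proportions(Group.CA_APP), 32, 5)
    no = expected_cohort_score(cal.proportions(Group.NO_APP), 31, 9)
    payload = {
        "expected_mean_ca_app": round(ca, 4),
        "expected_mean_no_app": round(no, 4),
        "difference_of_rounded_means": round(round(ca, 2) - round(no, 2), 2),
        "sample_size_per_group_d08_power09": sample_size_two_group(0.8, 0.05, 0.9),
        "sample_size_per_group_d08_power08": sample_size_two_group(0.8, 0.05, 0.8),
    }
    (OUT / "expected_scores.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(
        f"score-share consistency: expected means {ca:.3f} (aided) vs {no:.3f} (unaided), "
        f"difference of rounded means {payload['difference_of_rounded_means']}"
    )
    print(f"-> {OUT / 'expected_scores.json'}")


if __name__ == "__main__":
    main()
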