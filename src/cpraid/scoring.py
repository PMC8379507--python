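"""Rubric-based 0/1/2 scoring and the aggregate CPR performance score.

Each of the twelve performance variables maps to 0, 1 or 2 points.  For the
"smaller is better" time variables the bands come from a 15% margin rule:
score 2 up to the guideline threshold *T*, score 1 up to *T*(1+margin),
score 0 beyond — e.g. time to first shock scores 2 at <= 120 s, 1 at
121–138 s, 0 above.  Deviation variables use margin fractions of the
2-minute cycle (18 s / 36 s).  Count variables are scored by shortfall from
the scenario-length-dependent expectation.

A team's CPR performance score is the arithmetic mean of its non-missing
variable scores, on a 0–2 scale.  When the simulator's compression export
failed, depth and rate are missing and the mean runs over the remaining ten
variables; no other missingness pattern is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .metrics import (
    AlgorithmTargets,
    AmiodaroneClass,
    DEFAULT_TARGETS,
    PerformanceVariables,
    expected_count,
)

__all__ = [
    "Rubric",
    "ScoreCard",
    "VARIABLES",
    "margin_bands",
    "deviation_bands",
    "score_variable",
    "score_expected_count",
    "score_team",
    "cohort_table",
    "expected_cohort_score",
    "load_rubric",
    "default_rubric",
]

#: Canonical variable order (matches the study's results table).
VARIABLES = [
    "no_flow_fraction",
    "avg_depth",
    "avg_rate",
    "t_first_rhythm",
    "t_first_shock",
    "n_compressor_changes",
    "dev_compressor_change",
    "n_adrenaline",
    "dev_adrenaline",
    "n_rhythm_checks",
    "dev_rhythm",
    "amiodarone",
]

_COUNT_KIND = {
    "n_compressor_changes": "compressor_change",
    "n_adrenaline": "adrenaline",
    "n_rhythm_checks": "rhythm_check",
}

MISSING = "missing"


def margin_bands(threshold: float, margin: float) -> tuple[float, float]:
    """Band edges for a smaller-is-better variable with guideline threshold.

    Returns ``(score2_upper, score1_upper)`` = ``(T, T*(1+margin))``; e.g.
    (120, 0.15) → (120, 138).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    return threshold, threshold * (1.0 + margin)


def deviation_bands(cycle_target: float, margin: float) -> tuple[float, float]:
    """Band edges for a deviation variable: margin fractions of the cycle.

    (120, 0.15) → (18, 36): score 2 at <= 18 s mean delay, 1 at <= 36 s.
    """
    if cycle_target <= 0:
        raise ValueError(f"cycle_target must be > 0, got {cycle_target}")
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    return margin * cycle_target, 2.0 * margin * cycle_target


@dataclass(frozen=True)
class Rubric:
    """Per-variable band definitions plus the margin fraction."""

    variables: Mapping[str, dict]
    margin: float = 0.15

    def __post_init__(self) -> None:
        for name, spec in self.variables.items():
            kind = spec.get("kind")
            if kind == "lower_better":
                if spec["score1_max"] < spec["score2_max"]:
                    raise ValueError(f"{name}: score1_max below score2_max")
            elif kind == "range":
                lo, hi = spec["score2_range"]
                if hi < lo:
                    raise ValueError(f"{name}: empty score-2 range")
            elif kind not in ("count", "categorical"):
                raise ValueError(f"{name}: unknown band kind {kind!r}")


def load_rubric(path: Union[str, Path]) -> Rubric:
    raw = yaml.safe_load(Path(path).read_text())
    return Rubric(variables=raw["variables"], margin=float(raw.get("margin", 0.15)))


def default_rubric() -> Rubric:
    ref = resources.files("cpraid.data").joinpath("rubric.yaml")
    raw = yaml.safe_load(ref.read_text())
    return Rubric(variables=raw["variables"], margin=float(raw.get("margin", 0.15)))


def score_expected_count(observed: int, expected: int) -> int:
    """Score an action count against its scenario-length expectation.

    Meeting or exceeding the expectation scores 2, one action short scores 1,
    two or more short scores 0.
    """
    if observed < 0 or expected < 0:
        raise ValueError("counts must be >= 0")
    shortfall = expected - observed
    if shortfall <= 0:
        return 2
    if shortfall == 1:
        return 1
    return 0


def score_variable(
    variable: str,
    value,
    rubric: Optional[Rubric] = None,
    expected: Optional[int] = None,
):
    """Band lookup for one variable; returns 0 | 1 | 2 | "missing"."""
    rubric = rubric or default_rubric()
    if variable not in rubric.variables:
        raise KeyError(f"rubric does not define variable {variable!r}")
    spec = rubric.variables[variable]
    kind = spec["kind"]
    if value is None:
        if spec.get("missing_allowed"):
            return MISSING
        if "absent_score" in spec:
            return int(spec["absent_score"])
        raise ValueError(f"{variable}: value missing but rubric allows no missingness")
    if kind == "lower_better":
        if value <= spec["score2_max"]:
            return 2
        if value <= spec["score1_max"]:
            return 1
        return 0
    if kind == "range":
        lo, hi = spec["score2_range"]
        return 2 if lo <= value <= hi else 0
    if kind == "count":
        if expected is None:
            raise ValueError(f"{variable}: expected count required")
        return score_expected_count(int(value), int(expected))
    if kind == "categorical":
        key = value.value if isinstance(value, AmiodaroneClass) else str(value)
        return int(spec["mapping"][key])
    raise ValueError(f"unknown band kind {kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class ScoreCard:
    """Per-variable scores and the aggregate CPR performance score."""

    team_id: str
    scores: Mapping[str, object]  # variable -> 0|1|2|"missing"
    n_scored: int
    cpr_score: float


def score_team(
    vars: PerformanceVariables,
    rubric: Optional[Rubric] = None,
    targets: AlgorithmTargets = DEFAULT_TARGETS,
) -> ScoreCard:
    """Score all twelve variables and average the non-missing ones."""
    rubric = rubric or default_rubric()
    scores: dict[str, object] = {}
    for variable in VARIABLES:
        value = getattr(vars, variable)
        expected = None
        if variable in _COUNT_KIND:
            expected = expected_count(vars.scenario_length, _COUNT_KIND[variable], targets)
        scores[variable] = score_variable(variable, value, rubric, expected=expected)
    numeric = [s for s in scores.values() if s != MISSING]
    n_missing = len(scores) - len(numeric)
    if n_missing > 2:
        raise ValueError(
            f"team {vars.team_id}: {n_missing} missing variables; only the "
            "depth/rate pattern (<=2) is scoreable"
        )
    cpr = sum(numeric) / len(numeric)
    return ScoreCard(team_id=vars.team_id, scores=scores, n_scored=len(numeric), cpr_score=cpr)


def cards_to_frame(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        row = {"team_id": c.team_id, **{v: c.scores[v] for v in VARIABLES}}
        row["n_scored"] = c.n_scored
        row["cpr_score"] = c.cpr_score
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_table(
    cards: Sequence[ScoreCard],
    vars_by_team: Mapping[str, PerformanceVariables],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Group-level summary: score shares and raw mean (SD) per variable.

    Score shares are percentages over teams with the variable non-missing
    (so depth/rate percentages use only teams with compression data).
    """
    if not cards:
        raise ValueError("no scorecards")
    rows = []
    by_group: dict[str, list[ScoreCard]] = {}
    for c in cards:
        by_group.setdefault(groups[c.team_id], []).append(c)
    for group, members in sorted(by_group.items()):
        if not members:
            raise ValueError(f"empty group {group}")
        for variable in VARIABLES:
            scored = [c.scores[variable] for c in members if c.scores[variable] != MISSING]
            n = len(scored)
            raw = [
                getattr(vars_by_team[c.team_id], variable)
                for c in members
                if getattr(vars_by_team[c.team_id], variable) is not None
            ]
            numeric_raw = [v for v in raw if not isinstance(v, AmiodaroneClass)]
            s = pd.Series(numeric_raw, dtype=float)
            rows.append(
                {
                    "group": group,
                    "variable": variable,
                    "n": n,
                    "pct_score0": 100.0 * sum(1 for s_ in scored if s_ == 0) / n if n else float("nan"),
                    "pct_score1": 100.0 * sum(1 for s_ in scored if s_ == 1) / n if n else float("nan"),
                    "pct_score2": 100.0 * sum(1 for s_ in scored if s_ == 2) / n if n else float("nan"),
                    "raw_mean": s.mean() if len(s) else float("nan"),
                    "raw_sd": s.std(ddof=1) if len(s) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def expected_cohort_score(
    distributions: Mapping[str, tuple[float, float, float]],
    n_total: int,
    n_missing_depth_rate: int,
) -> float:
    """Expected group-mean CPR score implied by per-variable score shares.

    Each variable's expectation is Σ k·p(k).  Teams with compression data
    average all twelve variable expectations; teams without average the ten
    with depth/rate removed.  Returns the team-weighted group mean — the
    consistency check tying the score-share table to the reported group means.

    ``distributions`` maps each of the twelve variables to (p0, p1, p2);
    proportions may be percentages or fractions but must sum to 1 (±1%).
    """
    if set(distributions) != set(VARIABLES):
        missing = set(VARIABLES) - set(distributions)
        extra = set(distributions) - set(VARIABLES)
        raise ValueError(f"distributions mismatch: missing {missing}, extra {extra}")
    if not (0 <= n_missing_depth_rate <= n_total):
        raise ValueError("bad missing count")
    expectation: dict[str, float] = {}
    for variable, probs in distributions.items():
        p = [float(x) for x in probs]
        total = sum(p)
        if total <= 0:
            raise ValueError(f"{variable}: degenerate proportions")
        norm = [x / total for x in p]
        # percentages and fractions both allowed; only the *relative* sum check
        scale = 100.0 if total > 1.5 else 1.0
        if abs(total / scale - 1.0) > 0.01:
            raise ValueError(f"{variable}: proportions sum to {total / scale:.3f}, not 1")
        expectation[variable] = norm[1] + 2.0 * norm[2]
    mean12 = sum(expectation.values()) / 12.0
    ten = [v for k, v in expectation.items() if k not in ("avg_depth", "avg_rate")]
    mean10 = sum(ten) / 10.0
    n_full = n_total - n_missing_depth_rate
    return (n_full * mean12 + n_missing_depth_rate * mean10) / n_total
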