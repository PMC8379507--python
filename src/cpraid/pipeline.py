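"""End-to-end orchestration: manifest → metrics → scores → group statistics.

``run_pipeline`` reads (or generates) a cohort, drops analyst-flagged
exclusions, computes the twelve performance variables and scorecards per
team, builds the group-level score-share table, and compares the arms on the
CPR performance score and every continuous raw variable with the
normality-gated test path.  All outputs are plain delimited tables plus a
run log carrying the package version and a hash of the configuration, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .event_model import Group, load_cohort
from .metrics import AlgorithmTargets, DEFAULT_TARGETS, PerformanceVariables, compute_all
from .scoring import (
    ScoreCard,
    cards_to_frame,
    cohort_table,
    default_rubric,
    load_rubric,
    score_team,
)
from .stats import ComparisonResult, IccResult, compare_groups, icc_a1

__all__ = ["RunConfig", "CohortResult", "run_pipeline", "reliability_check",
           "RELIABILITY_VARIABLES", "metrics_frame"]

#: Continuous raw variables compared between arms (counts are rubric-only).
_COMPARED = [
    "no_flow_fraction",
    "avg_depth",
    "avg_rate",
    "t_first_rhythm",
    "t_first_shock",
    "dev_compressor_change",
    "dev_adrenaline",
    "dev_rhythm",
]

#: The six variables double-coded for the reliability check.
RELIABILITY_VARIABLES = [
    "no_flow_fraction",
    "t_first_rhythm",
    "t_first_shock",
    "dev_compressor_change",
    "dev_rhythm",
    "dev_adrenaline",
]


@dataclass(frozen=True)
class RunConfig:
    manifest: Path
    rubric_path: Optional[Path] = None
    targets: AlgorithmTargets = DEFAULT_TARGETS
    out_dir: Optional[Path] = None
    seed: int = 0


@dataclass(frozen=True)
class CohortResult:
    scorecards: pd.DataFrame
    variable_summary: pd.DataFrame
    comparisons: pd.DataFrame
    exclusions: pd.DataFrame
    per_team_vars: Mapping[str, PerformanceVariables]
    cards: Sequence[ScoreCard]


def metrics_frame(vars_list: Sequence[PerformanceVariables]) -> pd.DataFrame:
    """One delimited row per team with every performance variable."""
    rows = []
    for v in vars_list:
        rows.append(
            {
                "team_id": v.team_id,
                "no_flow_fraction_pct": v.no_flow_fraction,
                "avg_depth_cm": v.avg_depth,
                "avg_rate_per_min": v.avg_rate,
                "t_first_rhythm_s": v.t_first_rhythm,
                "t_first_shock_s": v.t_first_shock,
                "n_compressor_changes": v.n_compressor_changes,
                "dev_compressor_change_s": v.dev_compressor_change,
                "n_adrenaline": v.n_adrenaline,
                "dev_adrenaline_s": v.dev_adrenaline,
                "n_rhythm_checks": v.n_rhythm_checks,
                "dev_rhythm_s": v.dev_rhythm,
                "amiodarone": v.amiodarone.value,
                "scenario_length_s": v.scenario_length,
            }
        )
    return pd.DataFrame(rows)


def _comparison_row(variable: str, res: ComparisonResult) -> dict:
    return {
        "variable": variable,
        "test": res.test.value,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "effect_name": res.effect_name,
        "effect_size": res.effect_size,
        "mean_diff": res.mean_diff,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
    }


def run_pipeline(cfg: RunConfig) -> CohortResult:
    """Score a cohort and compare the arms; optionally write all tables."""
    rubric = default_rubric() if cfg.rubric_path is None else load_rubric(cfg.rubric_path)
    bundles = load_cohort(cfg.manifest)
    excl_rows, vars_list, cards = [], [], []
    groups: dict[str, str] = {}
    for log, series in bundles:
        if log.excluded:
            excl_rows.append(
                {"team_id": log.team_id, "group": log.group.value, "reason": log.exclusion_reason}
            )
            continue
        pv = compute_all(log, series, cfg.targets)
        vars_list.append(pv)
        cards.append(score_team(pv, rubric, cfg.targets))
        groups[log.team_id] = log.group.value
    by_group: dict[str, list[float]] = {}
    for c in cards:
        by_group.setdefault(groups[c.team_id], []).append(c.cpr_score)
    if any(len(v) < 2 for v in by_group.values()) or len(by_group) < 2:
        raise RuntimeError(
            "need >=2 non-excluded teams in each of two groups for comparisons; "
            f"got {({k: len(v) for k, v in by_group.items()})}"
        )
    vars_by_team = {v.team_id: v for v in vars_list}
    summary = cohort_table(cards, vars_by_team, groups)
    scorecards = cards_to_frame(cards)
    scorecards["group"] = scorecards["team_id"].map(groups)

    ga, gb = Group.CA_APP.value, Group.NO_APP.value
    comp_rows = [
        _comparison_row(
            "cpr_score", compare_groups(by_group[ga], by_group[gb])
        )
    ]
    mframe = metrics_frame(vars_list)
    mframe["group"] = mframe["team_id"].map(groups)
    col_of = {
        "no_flow_fraction": "no_flow_fraction_pct",
        "avg_depth": "avg_depth_cm",
        "avg_rate": "avg_rate_per_min",
        "t_first_rhythm": "t_first_rhythm_s",
        "t_first_shock": "t_first_shock_s",
        "dev_compressor_change": "dev_compressor_change_s",
        "dev_adrenaline": "dev_adrenaline_s",
        "dev_rhythm": "dev_rhythm_s",
    }
    for variable in _COMPARED:
        col = col_of[variable]
        a = mframe.loc[mframe.group == ga, col].dropna()
        b = mframe.loc[mframe.group == gb, col].dropna()
        if len(a) >= 2 and len(b) >= 2:
            comp_rows.append(_comparison_row(variable, compare_groups(a.to_numpy(), b.to_numpy())))
    comparisons = pd.DataFrame(comp_rows)
    exclusions = pd.DataFrame(excl_rows, columns=["team_id", "group", "reason"])

    result = CohortResult(
        scorecards=scorecards,
        variable_summary=summary,
        comparisons=comparisons,
        exclusions=exclusions,
        per_team_vars=vars_by_team,
        cards=cards,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scorecards.to_csv(out / "scorecards.csv", index=False)
        summary.to_csv(out / "variable_summary.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        mframe.to_csv(out / "metrics.csv", index=False)
        cfg_digest = hashlib.sha256(
            json.dumps(
                {
                    "manifest": str(cfg.manifest),
                    "rubric": str(cfg.rubric_path),
                    "targets": [cfg.targets.cycle_target, list(cfg.targets.adrenaline_window), cfg.targets.margin],
                    "seed": cfg.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "cpraid_version": __version__,
                    "config_sha256": cfg_digest,
                    "n_scored": len(cards),
                    "n_excluded": len(excl_rows),
                    "groups": {k: len(v) for k, v in by_group.items()},
                },
                indent=2,
            )
            + "\n"
        )
    return result


def reliability_check(coder1: pd.DataFrame, coder2: pd.DataFrame) -> IccResult:
    """ICC(A,1) between two coders over the six reliability variables.

    Both tables need a ``team_id`` column and the six metric columns (the
    :func:`metrics_frame` naming); every coded team-variable cell is one
    subject, the two coders are the raters.
    """
    cols = {
        "no_flow_fraction": "no_flow_fraction_pct",
        "t_first_rhythm": "t_first_rhythm_s",
        "t_first_shock": "t_first_shock_s",
        "dev_compressor_change": "dev_compressor_change_s",
        "dev_rhythm": "dev_rhythm_s",
        "dev_adrenaline": "dev_adrenaline_s",
    }
    a = coder1.set_index("team_id")
    b = coder2.set_index("team_id")
    if set(a.index) != set(b.index):
        raise ValueError("coder tables cover different team sets")
    teams = sorted(a.index)
    col_names = [cols[v] for v in RELIABILITY_VARIABLES]
    row1 = a.loc[teams, col_names].to_numpy(dtype=float).ravel()
    row2 = b.loc[teams, col_names].to_numpy(dtype=float).ravel()
    if np.isnan(row1).any() or np.isnan(row2).any():
        raise ValueError("reliability variables must be complete for both coders")
    return icc_a1(np.vstack([row1, row2]))
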