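"""Rubric scoring: band edges, margin rule, aggregate score, cohort tables."""

import numpy as np
import pytest

from cpraid.metrics import AmiodaroneClass, PerformanceVariables
from cpraid.scoring import (
    MISSING,
    VARIABLES,
    cohort_table,
    default_rubric,
    deviation_bands,
    expected_cohort_score,
    margin_bands,
    score_expected_count,
    score_team,
    score_variable,
)


def make_vars(**overrides):
    base = dict(
        team_id="T1",
        no_flow_fraction=10.0,
        avg_depth=5.5,
        avg_rate=110.0,
        t_first_rhythm=80.0,
        t_first_shock=110.0,
        n_compressor_changes=7,
        dev_compressor_change=10.0,
        n_adrenaline=3,
        dev_adrenaline=0.0,
        n_rhythm_checks=7,
        dev_rhythm=10.0,
        amiodarone=AmiodaroneClass.AFTER_THIRD_SHOCK,
        scenario_length=900.0,
    )
    base.update(overrides)
    return PerformanceVariables(**base)


class TestBands:
    def test_margin_rule_reproduces_138(self):
        assert margin_bands(120.0, 0.15) == (120.0, pytest.approx(138.0))

    def test_deviation_bands_18_36(self):
        assert deviation_bands(120.0, 0.15) == (pytest.approx(18.0), pytest.approx(36.0))

    def test_degenerate_zero_margin(self):
        assert margin_bands(100.0, 0.0) == (100.0, 100.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            margin_bands(0.0, 0.15)


class TestScoreVariable:
    @pytest.mark.parametrize(
        "variable, value, expected",
        [
            ("no_flow_fraction", 14.06, 2),
            ("no_flow_fraction", 15.0, 2),
            ("no_flow_fraction", 18.0, 1),
            ("no_flow_fraction", 20.5, 0),
            ("dev_rhythm", 31.0, 1),
            ("dev_rhythm", 18.0, 2),
            ("dev_rhythm", 36.5, 0),
            ("t_first_shock", 120.0, 2),
            ("t_first_shock", 130.0, 1),
            ("t_first_shock", 139.0, 0),
            ("avg_depth", 5.5, 2),
            ("avg_depth", 4.0, 0),
            ("avg_rate", 110.0, 2),
            ("avg_rate", 130.0, 0),
            ("dev_adrenaline", 0.0, 2),
            ("dev_adrenaline", 0.5, 0),  # no middle band
            ("amiodarone", AmiodaroneClass.NONE, 0),
            ("amiodarone", AmiodaroneClass.GIVEN, 1),
            ("amiodarone", AmiodaroneClass.AFTER_THIRD_SHOCK, 2),
        ],
    )
    def test_band_lookup(self, variable, value, expected):
        assert score_variable(variable, value) == expected

    def test_missing_depth_scores_missing(self):
        assert score_variable("avg_depth", None) == MISSING
        assert score_variable("avg_rate", None) == MISSING

    def test_never_shocked_scores_zero_not_missing(self):
        assert score_variable("t_first_shock", None) == 0

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            score_variable("tea_breaks", 3)

    def test_band_edges_exact_one_ulp(self):
        rubric = default_rubric()
        for variable in ("no_flow_fraction", "t_first_rhythm", "t_first_shock", "dev_rhythm", "dev_compressor_change"):
            spec = rubric.variables[variable]
            edge2, edge1 = spec["score2_max"], spec["score1_max"]
            assert edge1 > edge2
            assert score_variable(variable, edge2) == 2
            assert score_variable(variable, np.nextafter(edge2, np.inf)) == 1
            assert score_variable(variable, edge1) == 1
            assert score_variable(variable, np.nextafter(edge1, np.inf)) == 0

    def test_monotone_nonincreasing_for_smaller_is_better(self):
        for variable in ("no_flow_fraction", "t_first_rhythm", "dev_rhythm", "dev_adrenaline"):
            values = np.linspace(0.0, 60.0, 241)
            scores = [score_variable(variable, v) for v in values]
            assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestExpectedCountScore:
    @pytest.mark.parametrize(
        "observed, expected_n, score",
        [(7, 7, 2), (9, 7, 2), (6, 7, 1), (5, 7, 0), (0, 3, 0), (0, 0, 2)],
    )
    def test_shortfall_rule(self, observed, expected_n, score):
        assert score_expected_count(observed, expected_n) == score

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            score_expected_count(-1, 3)


class TestScoreTeam:
    def test_perfect_team_scores_two(self):
        card = score_team(make_vars())
        assert card.cpr_score == 2.0 and card.n_scored == 12

    def test_missing_depth_rate_averages_over_ten(self):
        card = score_team(make_vars(avg_depth=None, avg_rate=None))
        assert card.n_scored == 10
        assert card.cpr_score == 2.0

    def test_mixed_scores_mean(self):
        # scores (2,2,2,2,2,1,1,1,0,0,0,0) -> mean 13/12
        card = score_team(
            make_vars(
                no_flow_fraction=18.0,  # 1
                avg_depth=4.0,  # 0
                avg_rate=130.0,  # 0
                t_first_rhythm=130.0,  # 1
                t_first_shock=200.0,  # 0
                n_compressor_changes=6,  # expected 7 -> 1
                dev_adrenaline=5.0,  # 0
                amiodarone=AmiodaroneClass.AFTER_THIRD_SHOCK,  # 2
            )
        )
        assert sorted(card.scores.values(), reverse=True) == [2, 2, 2, 2, 2, 1, 1, 1, 0, 0, 0, 0]
        assert card.cpr_score == pytest.approx(13.0 / 12.0)

    def test_cpr_score_is_mean_of_nonmissing(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            card = score_team(
                make_vars(
                    no_flow_fraction=float(rng.uniform(0, 40)),
                    t_first_rhythm=float(rng.uniform(0, 300)),
                    t_first_shock=float(rng.uniform(0, 300)),
                    dev_rhythm=float(rng.uniform(0, 80)),
                    dev_compressor_change=float(rng.uniform(0, 80)),
                    n_rhythm_checks=int(rng.integers(0, 9)),
                )
            )
            numeric = [s for s in card.scores.values() if s != MISSING]
            assert card.cpr_score == pytest.approx(sum(numeric) / len(numeric))

    def test_unsupported_missingness_rejected(self):
        # only the depth/rate pattern is scoreable; a missing time-to-first-
        # rhythm has no rubric band and must error rather than silently skip
        with pytest.raises(ValueError, match="missing"):
            score_team(make_vars(avg_depth=None, avg_rate=None, t_first_rhythm=None))


class TestCohortTable:
    def _cards_and_vars(self, n, score2_on_no_flow):
        cards, vars_by_team, groups = [], {}, {}
        for i in range(n):
            good = i < score2_on_no_flow
            v = make_vars(team_id=f"T{i}", no_flow_fraction=10.0 if good else 25.0)
            card = score_team(v)
            cards.append(card)
            vars_by_team[v.team_id] = v
            groups[v.team_id] = "NO_APP"
        return cards, vars_by_team, groups

    def test_all_score_two_is_hundred_percent(self):
        cards, vbt, groups = self._cards_and_vars(5, 5)
        table = cohort_table(cards, vbt, groups)
        row = table[(table.variable == "no_flow_fraction")].iloc[0]
        assert row.pct_score2 == 100.0

    def test_20_of_31_scoring_two_is_64_5_percent(self):
        cards, vbt, groups = self._cards_and_vars(31, 20)
        table = cohort_table(cards, vbt, groups)
        row = table[(table.variable == "no_flow_fraction")].iloc[0]
        assert row.pct_score2 == pytest.approx(64.5, abs=0.05)

    def test_depth_percentages_only_over_teams_with_data(self):
        cards, vars_by_team, groups = [], {}, {}
        for i in range(4):
            v = make_vars(
                team_id=f"T{i}",
                avg_depth=None if i < 2 else 5.5,
                avg_rate=None if i < 2 else 110.0,
            )
            cards.append(score_team(v))
            vars_by_team[v.team_id] = v
            groups[v.team_id] = "CA_APP"
        table = cohort_table(cards, vars_by_team, groups)
        row = table[table.variable == "avg_depth"].iloc[0]
        assert row.n == 2 and row.pct_score2 == 100.0


class TestExpectedCohortScore:
    def test_degenerate_all_score_two(self):
        dists = {v: (0.0, 0.0, 1.0) for v in VARIABLES}
        assert expected_cohort_score(dists, 32, 5) == pytest.approx(2.0)

    def test_missing_teams_weighting(self):
        # depth/rate expectation 0, everything else 2: the 10-variable teams
        # average strictly higher than the 12-variable teams
        dists = {v: (0.0, 0.0, 1.0) for v in VARIABLES}
        dists["avg_depth"] = (1.0, 0.0, 0.0)
        dists["avg_rate"] = (1.0, 0.0, 0.0)
        full = expected_cohort_score(dists, 12, 0)
        half = expected_cohort_score(dists, 12, 6)
        all_missing = expected_cohort_score(dists, 12, 12)
        assert full < half < all_missing == pytest.approx(2.0)

    def test_bad_proportions_rejected(self):
        dists = {v: (0.0, 0.0, 1.0) for v in VARIABLES}
        dists["no_flow_fraction"] = (0.5, 0.4, 0.3)
        with pytest.raises(ValueError, match="sum"):
            expected_cohort_score(dists, 32, 5)
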