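"""Performance variables: worked examples plus oracle-equivalence properties.

The no-flow oracle sweeps 1-second bins over the arrest interval and counts
bins not covered by a compression segment — an independent, brute-force path
the interval arithmetic must agree with to binning tolerance.
"""

import numpy as np
import pytest

from cpraid.event_model import CompressionSeries, EventKind
from cpraid.metrics import (
    AlgorithmTargets,
    AmiodaroneClass,
    adrenaline_deviation,
    amiodarone_class,
    average_compression_quality,
    compression_segments,
    compute_all,
    expected_count,
    interval_deviation,
    no_flow_fraction,
    time_to_first,
)

from conftest import make_log, random_valid_log


def binned_no_flow(log, bin_s=0.01):
    """Independent oracle: fraction of fine time bins without compressions.

    The 10 ms bin width bounds the oracle's own discretization error (half a
    bin per segment boundary) well below the 0.2 percentage-point comparison
    tolerance even for short scenarios with many segments."""
    lo = log.arrival_time
    hi = log.scenario_end if log.rosc_time is None else min(log.rosc_time, log.scenario_end)
    edges = np.arange(lo, hi, bin_s)
    centers = edges + bin_s / 2.0
    covered = np.zeros(len(centers), dtype=bool)
    for s, e in compression_segments(log):
        covered |= (centers >= s) & (centers < e)
    return 100.0 * (1 - covered.mean())


class TestNoFlow:
    def test_full_coverage_gives_zero(self):
        log = make_log(
            [("COMPRESSIONS_START", 0.0), ("COMPRESSIONS_STOP", 200.0)], arrival=0.0, end=200.0
        )
        assert no_flow_fraction(log) == 0.0

    def test_hand_computed_pause(self):
        # arrest 0-200 s, flow [0,100) and [130,200): 30 s pause of 200 s
        log = make_log(
            [
                ("COMPRESSIONS_START", 0.0),
                ("COMPRESSIONS_STOP", 100.0),
                ("COMPRESSIONS_START", 130.0),
                ("COMPRESSIONS_STOP", 200.0),
            ],
            arrival=0.0,
            end=200.0,
        )
        assert no_flow_fraction(log) == pytest.approx(15.0)

    def test_no_compressions_is_total_no_flow(self):
        log = make_log([("ADRENALINE", 50.0)], arrival=0.0, end=200.0)
        assert no_flow_fraction(log) == 100.0

    def test_rosc_truncates_denominator(self):
        log = make_log(
            [("COMPRESSIONS_START", 0.0), ("COMPRESSIONS_STOP", 100.0)],
            arrival=0.0,
            end=200.0,
            rosc=100.0,
        )
        assert no_flow_fraction(log) == 0.0

    def test_zero_length_arrest_rejected(self):
        log = make_log([], arrival=100.0, end=100.0)
        with pytest.raises(ValueError):
            no_flow_fraction(log)

    def test_agrees_with_binned_oracle_on_random_logs(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            log = random_valid_log(rng)
            assert no_flow_fraction(log) == pytest.approx(binned_no_flow(log), abs=0.2)

    def test_removing_a_pause_never_increases_no_flow(self):
        events = [
            ("COMPRESSIONS_START", 0.0),
            ("COMPRESSIONS_STOP", 100.0),
            ("COMPRESSIONS_START", 130.0),
            ("COMPRESSIONS_STOP", 200.0),
        ]
        with_pause = no_flow_fraction(make_log(events, arrival=0.0, end=200.0))
        merged = no_flow_fraction(
            make_log(
                [("COMPRESSIONS_START", 0.0), ("COMPRESSIONS_STOP", 200.0)],
                arrival=0.0,
                end=200.0,
            )
        )
        assert merged <= with_pause


class TestTimeToFirst:
    def test_subtracts_arrival(self):
        log = make_log([("RHYTHM_CHECK_START", 118.0), ("RHYTHM_CHECK_END", 125.0)], arrival=20.0)
        assert time_to_first(log, EventKind.RHYTHM_CHECK_START) == pytest.approx(98.0)

    def test_zero_arrival(self):
        log = make_log([("DEFIBRILLATION", 120.0)], arrival=0.0)
        assert time_to_first(log, EventKind.DEFIBRILLATION) == pytest.approx(120.0)

    def test_never_shocked_team_is_absent(self):
        log = make_log([("ADRENALINE", 50.0)], arrival=0.0)
        assert time_to_first(log, EventKind.DEFIBRILLATION) is None


class TestIntervalDeviation:
    def test_conform_cycles_have_zero_deviation(self):
        dev, n = interval_deviation([120.0, 240.0, 360.0], 120.0, anchor=0.0)
        assert dev == 0.0 and n == 3

    def test_hand_computed_mean_delay(self):
        # intervals 120, 150, 130 -> delays 0, 30, 10 -> mean 13.33
        dev, n = interval_deviation([120.0, 270.0, 400.0], 120.0, anchor=0.0)
        assert dev == pytest.approx(40.0 / 3.0)
        assert n == 3

    def test_single_event_at_anchor_plus_target(self):
        dev, n = interval_deviation([140.0], 120.0, anchor=20.0)
        assert dev == 0.0 and n == 1

    def test_early_events_never_penalized(self):
        dev, _ = interval_deviation([30.0, 60.0, 90.0], 120.0, anchor=0.0)
        assert dev == 0.0

    def test_empty_sequence(self):
        assert interval_deviation([], 120.0, anchor=0.0) == (None, 0)

    def test_delay_monotonicity(self):
        # a delay at event i that propagates to all later events (how a real
        # slip in the cycle behaves) never decreases the mean deviation
        rng = np.random.default_rng(3)
        for _ in range(100):
            ts = np.sort(rng.uniform(0, 900, size=rng.integers(2, 8))).tolist()
            base, _ = interval_deviation(ts, 120.0, anchor=0.0)
            i = int(rng.integers(len(ts)))
            delta = float(rng.uniform(0, 200))
            shifted = ts[:i] + [t + delta for t in ts[i:]]
            moved, _ = interval_deviation(shifted, 120.0, anchor=0.0)
            assert moved >= base - 1e-9

    def test_brute_force_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            ts = np.sort(rng.uniform(10, 900, size=n)).tolist()
            anchor = float(rng.uniform(0, 10))
            target = float(rng.uniform(60, 240))
            dev, count = interval_deviation(ts, target, anchor=anchor)
            seq = [anchor] + ts
            expected = np.mean([max(0.0, b - a - target) for a, b in zip(seq, seq[1:])])
            assert dev == pytest.approx(expected)
            assert count == n


class TestAdrenalineDeviation:
    def test_hand_computed_window_deviations(self):
        # intervals 240 (conform), 360 (60 late) -> mean 30
        dev, n = adrenaline_deviation([100.0, 340.0, 700.0], (180.0, 300.0))
        assert dev == pytest.approx(30.0) and n == 3

    def test_four_minute_spacing_is_conform(self):
        dev, _ = adrenaline_deviation([0.0, 240.0, 480.0, 720.0], (180.0, 300.0))
        assert dev == 0.0

    def test_single_dose_carries_no_deviation(self):
        assert adrenaline_deviation([100.0], (180.0, 300.0)) == (0.0, 1)

    def test_too_early_measured_below_window(self):
        dev, _ = adrenaline_deviation([0.0, 100.0], (180.0, 300.0))
        assert dev == pytest.approx(80.0)

    def test_no_doses(self):
        assert adrenaline_deviation([], (180.0, 300.0)) == (0.0, 0)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "length, kind, expected",
        [
            (943.0, "rhythm_check", 7),  # floor(943/120)
            (943.0, "compressor_change", 7),
            (943.0, "adrenaline", 3),  # floor(943/240), 240 = window midpoint
            (120.0, "rhythm_check", 1),
            (100.0, "rhythm_check", 0),
        ],
    )
    def test_floor_rule(self, length, kind, expected):
        assert expected_count(length, kind) == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            expected_count(0.0, "rhythm_check")


class TestAmiodarone:
    def test_after_third_shock(self):
        log = make_log(
            [("DEFIBRILLATION", 100.0), ("DEFIBRILLATION", 220.0), ("DEFIBRILLATION", 340.0), ("AMIODARONE", 350.0)]
        )
        assert amiodarone_class(log) == AmiodaroneClass.AFTER_THIRD_SHOCK

    def test_before_any_shock_is_merely_given(self):
        log = make_log([("AMIODARONE", 50.0), ("DEFIBRILLATION", 100.0)])
        assert amiodarone_class(log) == AmiodaroneClass.GIVEN

    def test_after_fourth_shock_is_merely_given(self):
        log = make_log(
            [
                ("DEFIBRILLATION", 100.0),
                ("DEFIBRILLATION", 220.0),
                ("DEFIBRILLATION", 340.0),
                ("DEFIBRILLATION", 460.0),
                ("AMIODARONE", 470.0),
            ]
        )
        assert amiodarone_class(log) == AmiodaroneClass.GIVEN

    def test_none(self):
        assert amiodarone_class(make_log([])) == AmiodaroneClass.NONE


class TestCompressionQuality:
    def test_single_sample(self):
        s = CompressionSeries("T", ((0.0, 60.0, 5.0, 110.0),))
        assert average_compression_quality(s) == pytest.approx((5.0, 110.0))

    def test_duration_weighted_mean(self):
        s = CompressionSeries("T", ((0.0, 60.0, 4.0, 100.0), (60.0, 180.0, 5.5, 130.0)))
        depth, rate = average_compression_quality(s)
        assert depth == pytest.approx(5.0)
        assert rate == pytest.approx(120.0)

    def test_unavailable_series_is_absent(self):
        assert average_compression_quality(CompressionSeries("T", (), available=False)) is None
        assert average_compression_quality(None) is None


class TestComputeAll:
    def test_conform_log_has_zero_deviations(self):
        events = []
        t = 0.0
        for k in range(1, 7):
            events.append(("RHYTHM_CHECK_START", 120.0 * k))
            events.append(("RHYTHM_CHECK_END", 120.0 * k + 6.0))
            events.append(("COMPRESSOR_CHANGE", 120.0 * k))
        events += [("ADRENALINE", 180.0), ("ADRENALINE", 420.0), ("ADRENALINE", 660.0)]
        events += [("COMPRESSIONS_START", 5.0), ("COMPRESSIONS_STOP", 800.0)]
        events.sort(key=lambda e: e[1])
        pv = compute_all(make_log(events, arrival=0.0, end=800.0))
        assert pv.dev_rhythm == 0.0
        assert pv.dev_compressor_change == 0.0
        assert pv.dev_adrenaline == 0.0
        assert pv.no_flow_fraction < 15.0

    def test_never_shocked_team(self):
        log = make_log(
            [("COMPRESSIONS_START", 5.0), ("COMPRESSIONS_STOP", 800.0)], arrival=0.0, end=800.0
        )
        pv = compute_all(log)
        assert pv.t_first_shock is None
        assert pv.no_flow_fraction == pytest.approx(100.0 * 5.0 / 800.0)

    def test_no_adrenaline(self):
        pv = compute_all(make_log([("COMPRESSIONS_START", 5.0)], arrival=0.0, end=800.0))
        assert pv.n_adrenaline == 0 and pv.dev_adrenaline == 0.0

    def test_invariant_under_time_translation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            log = random_valid_log(rng)
            shifted = log.shifted(37.5)
            a, b = compute_all(log), compute_all(shifted)
            assert a.no_flow_fraction == pytest.approx(b.no_flow_fraction)
            assert a.dev_rhythm == pytest.approx(b.dev_rhythm)
            assert a.dev_adrenaline == pytest.approx(b.dev_adrenaline)
            assert (a.t_first_shock is None) == (b.t_first_shock is None)
            if a.t_first_shock is not None:
                assert a.t_first_shock == pytest.approx(b.t_first_shock)
            assert a.amiodarone == b.amiodarone
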