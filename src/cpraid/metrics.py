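"""The twelve CPR performance variables computed from one team's event log.

The variables measure how closely a team's timing follows the European
Resuscitation Council ALS algorithm for a shockable rhythm:

* **no-flow fraction** — share of the cardiac-arrest interval without chest
  compressions (lower is better; every pause costs perfusion);
* **average compression depth and rate** — from the simulator's per-period
  quality export, when it recorded;
* **time to first rhythm analysis / first shock** — from team arrival at the
  patient;
* **interval deviations** — rhythm checks and compressor changes are due every
  2 minutes; an interval of at most the target counts as conform (delay 0),
  anything longer contributes its excess in seconds.  Adrenaline redosing has
  a two-sided 3–5-minute window: doses spaced inside it are conform, too-early
  and too-late doses contribute their distance to the window;
* **expected action counts** — longer scenarios require more rhythm checks,
  compressor changes and adrenaline doses; observed counts are later scored
  against the expectation;
* **amiodarone timing** — none / given / given after the third shock (the
  guideline indication).

The cardiac-arrest interval runs from team arrival to ROSC or scenario end,
whichever is earlier; all "time to" variables subtract the arrival time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .event_model import CompressionSeries, EventKind, EventLog

__all__ = [
    "AmiodaroneClass",
    "AlgorithmTargets",
    "PerformanceVariables",
    "arrest_interval",
    "compression_segments",
    "no_flow_fraction",
    "time_to_first",
    "interval_deviation",
    "adrenaline_deviation",
    "expected_count",
    "amiodarone_class",
    "average_compression_quality",
    "compute_all",
]


class AmiodaroneClass(str, enum.Enum):
    NONE = "NONE"
    GIVEN = "GIVEN"
    AFTER_THIRD_SHOCK = "AFTER_THIRD_SHOCK"


@dataclass(frozen=True)
class AlgorithmTargets:
    """Guideline timing targets the metrics are measured against.

    ``cycle_target`` is the ALS 2-minute rhythm-check/compressor-change cycle;
    ``adrenaline_window`` the 3–5-minute redosing window.  ``margin`` is the
    tolerance fraction used downstream by the scoring rubric.  The expected
    action counts divide the scenario length by the cycle target (for checks
    and changes) or the window midpoint (for adrenaline); these floor rules
    are configuration and can be swapped for a different counting convention.
    """

    cycle_target: float = 120.0
    adrenaline_window: tuple[float, float] = (180.0, 300.0)
    margin: float = 0.15

    def __post_init__(self) -> None:
        low, high = self.adrenaline_window
        if not (0 < low < high):
            raise ValueError(f"bad adrenaline window {self.adrenaline_window}")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")


DEFAULT_TARGETS = AlgorithmTargets()


@dataclass(frozen=True)
class PerformanceVariables:
    """The twelve measured quantities for one team, plus scenario length.

    ``avg_depth``/``avg_rate`` are None when the simulator export failed;
    ``t_first_shock`` is None for a team that never defibrillated.
    """

    team_id: str
    no_flow_fraction: float
    avg_depth: Optional[float]
    avg_rate: Optional[float]
    t_first_rhythm: Optional[float]
    t_first_shock: Optional[float]
    n_compressor_changes: int
    dev_compressor_change: float
    n_adrenaline: int
    dev_adrenaline: float
    n_rhythm_checks: int
    dev_rhythm: float
    amiodarone: AmiodaroneClass
    scenario_length: float


def arrest_interval(log: EventLog) -> tuple[float, float]:
    """Cardiac-arrest interval for denominator purposes: arrival → ROSC/end."""
    end = log.scenario_end if log.rosc_time is None else min(log.rosc_time, log.scenario_end)
    return (log.arrival_time, end)


def compression_segments(log: EventLog) -> list[tuple[float, float]]:
    """Half-open [start, stop) compression segments; an unterminated final
    segment is closed at scenario end."""
    segments: list[tuple[float, float]] = []
    start: Optional[float] = None
    for e in log.events:
        if e.kind == EventKind.COMPRESSIONS_START:
            start = e.timestamp
        elif e.kind == EventKind.COMPRESSIONS_STOP and start is not None:
            segments.append((start, e.timestamp))
            start = None
    if start is not None:
        segments.append((start, log.scenario_end))
    return segments


def no_flow_fraction(log: EventLog) -> float:
    """Percentage of the arrest interval without chest compressions."""
    lo, hi = arrest_interval(log)
    duration = hi - lo
    if duration <= 0:
        raise ValueError(f"empty arrest interval [{lo}, {hi}]")
    flow = 0.0
    for s, e in compression_segments(log):
        flow += max(0.0, min(e, hi) - max(s, lo))
    return 100.0 * (duration - flow) / duration


def time_to_first(log: EventLog, kind: EventKind) -> Optional[float]:
    """Seconds from arrival to the first event of ``kind``; None if absent."""
    ts = log.timestamps_of(kind)
    return None if not ts else ts[0] - log.arrival_time


def interval_deviation(
    timestamps: Sequence[float], target: float, anchor: Optional[float] = None
) -> tuple[Optional[float], int]:
    """Mean one-sided delay of a repeated action against its cycle target.

    Each interval between consecutive events (the first measured from
    ``anchor`` — team arrival — when given) in excess of ``target`` counts its
    excess in seconds; intervals at or under target are conform with delay 0.
    Returns ``(mean delay, number of events)``; ``(None, 0)`` when there are
    no events.
    """
    ts = sorted(timestamps)
    if not ts:
        return None, 0
    if anchor is not None:
        intervals = [b - a for a, b in zip([anchor] + ts[:-1], ts)]
    else:
        intervals = [b - a for a, b in zip(ts[:-1], ts[1:])]
    devs = [max(0.0, iv - target) for iv in intervals]
    return (sum(devs) / len(devs) if devs else 0.0), len(ts)


def adrenaline_deviation(
    timestamps: Sequence[float], window: tuple[float, float] = (180.0, 300.0)
) -> tuple[float, int]:
    """Mean distance of inter-dose intervals from the redosing window.

    The first dose is exempt (the window constrains spacing between doses).
    An interval shorter than the window start is too early by the shortfall,
    longer than the window end too late by the excess, inside conform (0).
    """
    low, high = window
    ts = sorted(timestamps)
    if len(ts) <= 1:
        return 0.0, len(ts)
    devs = []
    for a, b in zip(ts[:-1], ts[1:]):
        iv = b - a
        if iv < low:
            devs.append(low - iv)
        elif iv > high:
            devs.append(iv - high)
        else:
            devs.append(0.0)
    return sum(devs) / len(devs), len(ts)


def expected_count(
    scenario_length: float, kind: str, targets: AlgorithmTargets = DEFAULT_TARGETS
) -> int:
    """Guideline-expected number of actions for a scenario of this length.

    Rhythm checks and compressor changes recur every cycle; adrenaline every
    window midpoint (4 min).  A floor rule: a 943 s scenario expects
    floor(943/120) = 7 rhythm checks.
    """
    if scenario_length <= 0:
        raise ValueError(f"scenario_length must be > 0, got {scenario_length}")
    if kind in ("rhythm_check", "compressor_change"):
        period = targets.cycle_target
    elif kind == "adrenaline":
        low, high = targets.adrenaline_window
        period = (low + high) / 2.0
    else:
        raise ValueError(f"unknown action kind {kind!r}")
    return int(math.floor(scenario_length / period))


def amiodarone_class(log: EventLog) -> AmiodaroneClass:
    """NONE / GIVEN / AFTER_THIRD_SHOCK — the guideline indication is a first
    dose between the third and fourth defibrillation."""
    amio = log.timestamps_of(EventKind.AMIODARONE)
    if not amio:
        return AmiodaroneClass.NONE
    shocks = log.timestamps_of(EventKind.DEFIBRILLATION)
    first = amio[0]
    if len(shocks) >= 3 and first >= shocks[2] and (len(shocks) < 4 or first < shocks[3]):
        return AmiodaroneClass.AFTER_THIRD_SHOCK
    return AmiodaroneClass.GIVEN


def average_compression_quality(
    series: Optional[CompressionSeries],
) -> Optional[tuple[float, float]]:
    """Duration-weighted mean (depth cm, rate /min); None when unavailable."""
    if series is None or not series.available or not series.samples:
        return None
    total = sum(e - s for s, e, _, _ in series.samples)
    depth = sum((e - s) * d for s, e, d, _ in series.samples) / total
    rate = sum((e - s) * r for s, e, _, r in series.samples) / total
    return depth, rate


def compute_all(
    log: EventLog,
    series: Optional[CompressionSeries] = None,
    targets: AlgorithmTargets = DEFAULT_TARGETS,
) -> PerformanceVariables:
    """Populate every performance variable for one team."""
    quality = average_compression_quality(series)
    rhythm_ts = log.timestamps_of(EventKind.RHYTHM_CHECK_START)
    change_ts = log.timestamps_of(EventKind.COMPRESSOR_CHANGE)
    adren_ts = log.timestamps_of(EventKind.ADRENALINE)
    dev_rhythm, n_rhythm = interval_deviation(rhythm_ts, targets.cycle_target, anchor=log.arrival_time)
    dev_change, n_change = interval_deviation(change_ts, targets.cycle_target, anchor=log.arrival_time)
    dev_adren, n_adren = adrenaline_deviation(adren_ts, targets.adrenaline_window)
    return PerformanceVariables(
        team_id=log.team_id,
        no_flow_fraction=no_flow_fraction(log),
        avg_depth=None if quality is None else quality[0],
        avg_rate=None if quality is None else quality[1],
        t_first_rhythm=time_to_first(log, EventKind.RHYTHM_CHECK_START),
        t_first_shock=time_to_first(log, EventKind.DEFIBRILLATION),
        n_compressor_changes=n_change,
        dev_compressor_change=0.0 if dev_change is None else dev_change,
        n_adrenaline=n_adren,
        dev_adrenaline=dev_adren,
        n_rhythm_checks=n_rhythm,
        dev_rhythm=0.0 if dev_rhythm is None else dev_rhythm,
        amiodarone=amiodarone_class(log),
        scenario_length=log.scenario_end,
    )
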