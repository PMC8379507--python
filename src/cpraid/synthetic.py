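"""Synthetic resuscitation cohorts at two fidelity levels.

**Calibrated score sampling** draws per-variable 0/1/2 scores directly from a
published score-share table (a statistical twin of the cohort summaries):
each team's variable scores are independent draws from that variable's
(p0, p1, p2), with a configured number of teams per cohort missing the
compression depth/rate variables (scored on the remaining ten).  This level
exercises everything downstream of scoring without any event data.

**Mechanistic event-log simulation** generates full timestamped logs of team
behavior in a persistent-VF arrest: an early first rhythm check, then a
2-minute check cycle perturbed by a one-sided delay (aided teams respond to
the app's due alert with a small latency; unaided teams drift), compression
pauses around checks, a shock after each check, adrenaline redosing with
group-specific spacing, compressor changes at checks with occasional skips,
and amiodarone after the third shock with imperfect compliance.  Aided runs
drive the :mod:`cpraid.aid_engine` state machine and log the button presses.
Delay distributions are normals truncated at zero, matching the one-sided
max(0, .) deviation definition.

Every simulated log passes :func:`cpraid.event_model.validate_log`; all
randomness flows from explicit seeds via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from . import aid_engine as aid
from .event_model import (
    CompressionSeries,
    Event,
    EventKind,
    EventLog,
    Group,
    write_compression_series,
    write_event_log,
    write_manifest,
)
from .scoring import MISSING, ScoreCard, VARIABLES

__all__ = [
    "CalibrationTable",
    "BehaviorConfig",
    "load_calibration",
    "table2_calibration",
    "sample_scorecards",
    "aided_config",
    "unaided_config",
    "simulate_team_log",
    "simulate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# Calibrated score sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationTable:
    """Per-group score proportions, raw summaries and missingness counts."""

    groups: Mapping[str, dict]

    def proportions(self, group: str | Group) -> dict[str, tuple[float, float, float]]:
        g = self.groups[Group(group).value]
        return {v: tuple(spec["p"]) for v, spec in g["variables"].items()}

    def n_teams(self, group: str | Group) -> int:
        return int(self.groups[Group(group).value]["n_teams"])

    def n_missing(self, group: str | Group) -> int:
        return int(self.groups[Group(group).value]["missing_depth_rate"])


def load_calibration(path: str | Path) -> CalibrationTable:
    raw = yaml.safe_load(Path(path).read_text())
    return CalibrationTable(groups=raw["groups"])


def table2_calibration() -> CalibrationTable:
    """The packaged default calibration (published cohort score shares)."""
    ref = resources.files("cpraid.data").joinpath("calibration.yaml")
    return CalibrationTable(groups=yaml.safe_load(ref.read_text())["groups"])


def sample_scorecards(
    cal: CalibrationTable,
    group: str | Group,
    seed,
    n_teams: Optional[int] = None,
    n_missing: Optional[int] = None,
) -> list[ScoreCard]:
    """Draw one cohort of scorecards from a calibration table.

    Each variable score is an independent draw from that variable's
    (p0, p1, p2); ``n_missing`` randomly chosen teams get depth/rate set
    missing and are scored over the remaining ten variables.  Reproducible:
    the same seed yields the same cohort.
    """
    rng = np.random.default_rng(seed)
    props = cal.proportions(group)
    n = cal.n_teams(group) if n_teams is None else int(n_teams)
    miss = cal.n_missing(group) if n_missing is None else int(n_missing)
    if not (0 <= miss <= n):
        raise ValueError(f"n_missing {miss} outside [0, {n}]")
    # cumulative probabilities per variable, drawn vectorized over teams
    scores = np.empty((n, len(VARIABLES)), dtype=int)
    for j, variable in enumerate(VARIABLES):
        p = np.asarray(props[variable], dtype=float)
        total = p.sum()
        scale = 100.0 if total > 1.5 else 1.0
        if abs(total / scale - 1.0) > 0.01:
            raise ValueError(f"{variable}: proportions sum to {total / scale:.3f}, not 1")
        cum = np.cumsum(p / total)
        scores[:, j] = np.searchsorted(cum, rng.random(n), side="right")
    missing_teams = set(rng.choice(n, size=miss, replace=False).tolist())
    cards = []
    for i in range(n):
        per_var: dict[str, object] = {v: int(scores[i, j]) for j, v in enumerate(VARIABLES)}
        if i in missing_teams:
            per_var["avg_depth"] = MISSING
            per_var["avg_rate"] = MISSING
        numeric = [s for s in per_var.values() if s != MISSING]
        cards.append(
            ScoreCard(
                team_id=f"{Group(group).value}_{i + 1:03d}",
                scores=per_var,
                n_scored=len(numeric),
                cpr_score=sum(numeric) / len(numeric),
            )
        )
    return cards


# ---------------------------------------------------------------------------
# Mechanistic event-log simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorConfig:
    """Timing-behavior parameters for one study arm.

    All (mean, sd) pairs are seconds unless noted; delay-like quantities are
    drawn from normals truncated at 0 (deviations are one-sided).  Defaults
    for each arm come from :func:`aided_config` / :func:`unaided_config` and
    are calibrated so cohort raw-value summaries land near the published
    group means — e.g. rhythm-cycle delay ~12 s (aided, alert-response
    latency) vs ~30 s (unaided drift).
    """

    group: Group
    n_teams: int = 32
    scenario_length: tuple[float, float] = (943.0, 110.0)
    arrival: tuple[float, float] = (20.0, 5.0)
    first_check: tuple[float, float] = (74.0, 30.0)  # s after arrival
    cycle_delay: tuple[float, float] = (12.0, 10.0)  # added to the 120 s cycle
    check_duration: tuple[float, float] = (8.0, 2.0)
    pause_duration: tuple[float, float] = (15.0, 4.0)  # hands-off time per check
    initial_delay: tuple[float, float] = (15.0, 8.0)  # arrival -> compressions
    shock_after_check: tuple[float, float] = (37.0, 18.0)  # first shock lag
    first_adrenaline: tuple[float, float] = (180.0, 60.0)  # s after arrival
    adrenaline_interval: tuple[float, float] = (270.0, 60.0)
    change_skip_prob: float = 0.12
    amiodarone_compliance: float = 0.81
    depth: tuple[float, float] = (4.6, 1.0)  # cm
    rate: tuple[float, float] = (121.0, 7.0)  # min^-1
    p_missing_compression: float = 5.0 / 32.0
    extra_press_per_min: float = 0.75  # aided only: non-documentation presses
    rosc_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_teams < 1:
            raise ValueError("n_teams must be >= 1")
        for name in (
            "scenario_length", "arrival", "first_check", "cycle_delay",
            "check_duration", "pause_duration", "initial_delay",
            "shock_after_check", "first_adrenaline", "adrenaline_interval",
            "depth", "rate",
        ):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        for name in ("change_skip_prob", "amiodarone_compliance", "p_missing_compression"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be a probability")


def aided_config(n_teams: int = 32, **overrides) -> BehaviorConfig:
    """Cognitive-aid arm: small alert-response latency, tight adrenaline spacing."""
    return BehaviorConfig(group=Group.CA_APP, n_teams=n_teams, **overrides)


def unaided_config(n_teams: int = 31, **overrides) -> BehaviorConfig:
    """No-app arm: cycle drift without alerts, looser spacing, more misses."""
    defaults = dict(
        scenario_length=(902.0, 100.0),
        first_check=(98.0, 50.0),
        cycle_delay=(27.0, 31.0),
        pause_duration=(18.0, 6.0),
        initial_delay=(20.0, 10.0),
        adrenaline_interval=(300.0, 110.0),
        change_skip_prob=0.22,
        amiodarone_compliance=0.74,
        depth=(4.0, 1.0),
        rate=(119.0, 12.0),
        p_missing_compression=9.0 / 31.0,
        extra_press_per_min=0.0,
    )
    defaults.update(overrides)
    return BehaviorConfig(group=Group.NO_APP, n_teams=n_teams, **defaults)


def truncnorm_mean(mean: float, sd: float) -> float:
    """E[max(0, X)] for X ~ N(mean, sd): the expected one-sided delay."""
    if sd == 0:
        return max(0.0, mean)
    z = mean / sd
    phi = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    Phi = 0.5 * (1 + math.erf(z / math.sqrt(2)))
    return mean * Phi + sd * phi


def _pos(rng: np.random.Generator, mean_sd: tuple[float, float], floor: float = 0.0) -> float:
    mean, sd = mean_sd
    return max(floor, float(rng.normal(mean, sd)) if sd > 0 else mean)


def simulate_team_log(
    cfg: BehaviorConfig, team_seed, team_id: Optional[str] = None
) -> tuple[EventLog, Optional[CompressionSeries], Optional[list[aid.InteractionRecord]]]:
    """Simulate one team's scenario.

    Returns the event log, the compression-quality series (None when the
    simulated export "failed"), and — for the aided arm — the app interaction
    records produced by replaying the team's documentation presses through
    the aid engine.
    """
    rng = np.random.default_rng(team_seed)
    aided = cfg.group == Group.CA_APP
    arrival = _pos(rng, cfg.arrival)
    length = _pos(rng, cfg.scenario_length, floor=400.0)
    end = arrival + length
    events: list[Event] = []

    # Rhythm checks: early first analysis, then the 2-min cycle + one-sided delay.
    checks: list[tuple[float, float]] = []
    t = arrival + _pos(rng, cfg.first_check, floor=5.0)
    while t < end - 30.0:
        dur = _pos(rng, cfg.check_duration, floor=3.0)
        checks.append((t, min(t + dur, end)))
        t = t + 120.0 + max(0.0, float(rng.normal(*cfg.cycle_delay)))
    shocks: list[float] = []
    changes: list[float] = []
    for i, (cs, ce) in enumerate(checks):
        lag = cfg.shock_after_check if i == 0 else (5.0, 2.0)
        shock_t = ce + _pos(rng, lag, floor=1.0)
        if shock_t < end:
            shocks.append(shock_t)
        if rng.random() > cfg.change_skip_prob:
            changes.append(min(ce + 1.0, end))

    # Adrenaline: first dose, then group-specific redosing interval.
    adren: list[float] = []
    t = arrival + _pos(rng, cfg.first_adrenaline, floor=60.0)
    while t < end - 10.0:
        adren.append(t)
        t = t + _pos(rng, cfg.adrenaline_interval, floor=60.0)

    amio: Optional[float] = None
    if len(shocks) >= 3 and rng.random() < cfg.amiodarone_compliance:
        candidate = shocks[2] + _pos(rng, (30.0, 10.0), floor=5.0)
        if len(shocks) >= 4:
            candidate = min(candidate, (shocks[2] + shocks[3]) / 2.0)
        if candidate < end:
            amio = candidate

    # Compression segments: continuous flow except a hands-off window at each
    # check (analysis + charge + shock) and the initial delay after arrival.
    pauses: list[tuple[float, float]] = []
    for cs, ce in checks:
        pauses.append((cs, min(cs + _pos(rng, cfg.pause_duration, floor=4.0), end)))
    pauses.sort()
    merged: list[tuple[float, float]] = []
    for s, e in pauses:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    comp_start = arrival + _pos(rng, cfg.initial_delay, floor=2.0)
    segments: list[tuple[float, float]] = []
    cursor = comp_start
    for s, e in merged:
        if s > cursor:
            segments.append((cursor, min(s, end)))
        cursor = max(cursor, e)
    if cursor < end:
        segments.append((cursor, end))
    segments = [(s, e) for s, e in segments if e - s > 1.0]

    for s, e in segments:
        events.append(Event(EventKind.COMPRESSIONS_START, s))
        events.append(Event(EventKind.COMPRESSIONS_STOP, e))
    for cs, ce in checks:
        events.append(Event(EventKind.RHYTHM_CHECK_START, cs))
        events.append(Event(EventKind.RHYTHM_CHECK_END, ce))
    events += [Event(EventKind.DEFIBRILLATION, t) for t in shocks]
    events += [Event(EventKind.ADRENALINE, t) for t in adren]
    events += [Event(EventKind.COMPRESSOR_CHANGE, t) for t in changes]
    if amio is not None:
        events.append(Event(EventKind.AMIODARONE, amio))
    if cfg.rosc_time is not None and arrival < cfg.rosc_time < end:
        events.append(Event(EventKind.ROSC, cfg.rosc_time))
    events.sort(key=lambda e: (e.timestamp, e.kind.value))

    log = EventLog(
        team_id=team_id or f"{cfg.group.value}_{int(np.random.default_rng(team_seed).integers(1e6)):06d}",
        group=cfg.group,
        arrival_time=arrival,
        scenario_end=end,
        events=tuple(events),
        rosc_time=cfg.rosc_time if cfg.rosc_time is not None and arrival < cfg.rosc_time < end else None,
    )

    series: Optional[CompressionSeries] = None
    if rng.random() >= cfg.p_missing_compression:
        samples = []
        for s, e in segments:
            depth = min(9.5, max(0.5, float(rng.normal(*cfg.depth))))
            rate = min(199.0, max(30.0, float(rng.normal(*cfg.rate))))
            samples.append((s, e, round(depth, 2), round(rate, 1)))
        series = CompressionSeries(team_id=log.team_id, samples=tuple(samples), available=True)

    interactions: Optional[list[aid.InteractionRecord]] = None
    if aided:
        interactions = _replay_through_engine(log, amio, rng, cfg)
    return log, series, interactions


def _replay_through_engine(
    log: EventLog, amio: Optional[float], rng: np.random.Generator, cfg: BehaviorConfig
) -> list[aid.InteractionRecord]:
    """Drive the aid engine with the team's documentation presses."""
    presses: list[tuple[float, aid.Button]] = []
    for e in log.events:
        if e.kind == EventKind.RHYTHM_CHECK_START:
            presses.append((e.timestamp, aid.Button.RHYTHM_CHECK))
        elif e.kind == EventKind.DEFIBRILLATION:
            presses.append((e.timestamp, aid.Button.DEFIB))
        elif e.kind == EventKind.ADRENALINE:
            presses.append((e.timestamp, aid.Button.ADRENALINE))
        elif e.kind == EventKind.AMIODARONE:
            presses.append((e.timestamp, aid.Button.AMIODARONE))
        elif e.kind == EventKind.ROSC:
            presses.append((e.timestamp, aid.Button.HDM_ROSC_TOGGLE))
    duration_min = (log.scenario_end - log.arrival_time) / 60.0
    n_extra = int(rng.poisson(cfg.extra_press_per_min * duration_min))
    extra_buttons = [
        aid.Button.HS_TS_EXPAND,
        aid.Button.OTHER_INTERVENTION_1,
        aid.Button.OTHER_INTERVENTION_2,
        aid.Button.OTHER_INTERVENTION_3,
    ]
    for _ in range(n_extra):
        t = float(rng.uniform(log.arrival_time, log.scenario_end))
        presses.append((t, extra_buttons[int(rng.integers(len(extra_buttons)))]))
    presses.sort(key=lambda p: p[0])
    state = aid.init_state()
    clock = log.arrival_time
    records: list[aid.InteractionRecord] = []
    for t, button in presses:
        state = aid.advance(state, t - clock)
        clock = t
        state, rec = aid.press(state, button, t - log.arrival_time)
        records.append(rec)
    return records


def simulate_cohort(
    cfg: BehaviorConfig, master_seed
) -> list[tuple[EventLog, Optional[CompressionSeries], Optional[list[aid.InteractionRecord]]]]:
    """Simulate ``cfg.n_teams`` independent teams with derived per-team seeds."""
    children = np.random.SeedSequence(master_seed).spawn(cfg.n_teams)
    out = []
    for i, child in enumerate(children):
        team_id = f"{cfg.group.value}_{i + 1:03d}"
        out.append(simulate_team_log(cfg, child, team_id=team_id))
    return out


def write_cohort(
    bundles: Sequence[tuple[EventLog, Optional[CompressionSeries], Optional[list]]],
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write a simulated cohort in the event-model dialect; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for log, series, _ in bundles:
        event_file = f"{log.team_id}_events.csv"
        write_event_log(log, out_dir / event_file)
        comp_file = ""
        if series is not None:
            comp_file = f"{log.team_id}_compressions.csv"
            write_compression_series(series, out_dir / comp_file)
        rows.append(
            {
                "team_id": log.team_id,
                "group": log.group.value,
                "arrival_time_s": log.arrival_time,
                "scenario_end_s": log.scenario_end,
                "event_file": event_file,
                "compression_file": comp_file,
                "excluded": log.excluded,
                "exclusion_reason": log.exclusion_reason,
            }
        )
    manifest = out_dir / manifest_name
    write_manifest(rows, manifest)
    return manifest
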