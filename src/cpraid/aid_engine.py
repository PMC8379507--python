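"""Headless re-implementation of the cognitive-aid app's timer and alert logic.

The tablet app the study evaluated is an *attentional* aid: it shows a timer
since arrival at the patient, a timer since the last documented heart-rhythm
check (with a prepare alert at 01:40 and a due alert at 02:00, when the next
2-minute ALS cycle ends), a timer since the last adrenaline dose (orange once
the 3–5-minute redosing window opens), a compressor-change reminder tied to
the rhythm-check cycle, and an amiodarone reminder after every third
defibrillation.  Team members document actions by pressing buttons, which
resets the corresponding timer.

This module models that logic as a pure state machine: no clock, no GUI.
Time moves only through :func:`advance` and documentation happens only through
:func:`press`, so any press/advance trace replays to an identical state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

__all__ = [
    "AlertLevel",
    "AdrenalineAlert",
    "CompressionsMode",
    "Button",
    "AidConfig",
    "AidState",
    "InteractionRecord",
    "init_state",
    "advance",
    "press",
    "adrenaline_alert_rule",
    "interactions_per_minute",
]


class AlertLevel(str, enum.Enum):
    NONE = "NONE"
    PREPARE = "PREPARE"  # orange background, 01:40
    DUE = "DUE"  # red background, 02:00


class AdrenalineAlert(str, enum.Enum):
    NONE = "NONE"
    CONSIDER = "CONSIDER"  # orange: redosing window open


class CompressionsMode(str, enum.Enum):
    CPR = "CPR"
    ROSC = "ROSC"


class Button(str, enum.Enum):
    RHYTHM_CHECK = "RHYTHM_CHECK"
    DEFIB = "DEFIB"
    ADRENALINE = "ADRENALINE"
    AMIODARONE = "AMIODARONE"
    HDM_ROSC_TOGGLE = "HDM_ROSC_TOGGLE"
    OTHER_INTERVENTION_1 = "OTHER_INTERVENTION_1"
    OTHER_INTERVENTION_2 = "OTHER_INTERVENTION_2"
    OTHER_INTERVENTION_3 = "OTHER_INTERVENTION_3"
    HS_TS_EXPAND = "HS_TS_EXPAND"


@dataclass(frozen=True)
class AidConfig:
    """Alert thresholds in seconds.

    Defaults follow the app's printed timings: 01:40 → prepare, 02:00 → due
    for the rhythm-check cycle, and the compressor-change icon appearing with
    the 01:40 alert.  The app does not print when the adrenaline timer turns
    orange; 180 s — the opening of the guideline 3–5-minute redosing window —
    is the configurable default.
    """

    rhythm_prepare_s: float = 100.0
    rhythm_due_s: float = 120.0
    change_prompt_s: float = 100.0
    adrenaline_consider_s: float = 180.0


DEFAULT_CONFIG = AidConfig()


@dataclass(frozen=True)
class InteractionRecord:
    """One physical interaction: a button press at a timestamp."""

    timestamp: float
    button: Button


@dataclass(frozen=True)
class AidState:
    """The engine's full state at an instant.

    Timers count seconds since their anchor event; ``t_adrenaline`` is None
    until the first dose is documented.  Alert fields are pure functions of
    the timers except ``amiodarone_prompt``, which latches from each third
    defibrillation until amiodarone is documented.
    """

    t_arrival: float = 0.0
    t_rhythm: float = 0.0
    t_adrenaline: Optional[float] = None
    defib_count: int = 0
    compressions_mode: CompressionsMode = CompressionsMode.CPR
    rhythm_alert: AlertLevel = AlertLevel.NONE
    compressor_change_prompt: bool = False
    adrenaline_alert: AdrenalineAlert = AdrenalineAlert.NONE
    amiodarone_prompt: bool = False


def init_state() -> AidState:
    """State at the moment the team arrives and starts the app."""
    return AidState()


def _recompute_alerts(state: AidState, config: AidConfig) -> AidState:
    if state.t_rhythm >= config.rhythm_due_s:
        rhythm = AlertLevel.DUE
    elif state.t_rhythm >= config.rhythm_prepare_s:
        rhythm = AlertLevel.PREPARE
    else:
        rhythm = AlertLevel.NONE
    return replace(
        state,
        rhythm_alert=rhythm,
        compressor_change_prompt=state.t_rhythm >= config.change_prompt_s,
        adrenaline_alert=adrenaline_alert_rule(state.t_adrenaline, config)
        if state.t_adrenaline is not None
        else AdrenalineAlert.NONE,
    )


def advance(state: AidState, dt: float, config: AidConfig = DEFAULT_CONFIG) -> AidState:
    """Move time forward by ``dt`` seconds; pure, no side effects."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    moved = replace(
        state,
        t_arrival=state.t_arrival + dt,
        t_rhythm=state.t_rhythm + dt,
        t_adrenaline=None if state.t_adrenaline is None else state.t_adrenaline + dt,
    )
    return _recompute_alerts(moved, config)


def press(
    state: AidState,
    button: Button,
    timestamp: float,
    config: AidConfig = DEFAULT_CONFIG,
) -> tuple[AidState, InteractionRecord]:
    """Document an action.  Every press is legal at every time, as in the app."""
    button = Button(button)
    record = InteractionRecord(timestamp=timestamp, button=button)
    if button == Button.RHYTHM_CHECK:
        state = replace(state, t_rhythm=0.0)
    elif button == Button.ADRENALINE:
        state = replace(state, t_adrenaline=0.0)
    elif button == Button.DEFIB:
        n = state.defib_count + 1
        state = replace(
            state,
            defib_count=n,
            amiodarone_prompt=state.amiodarone_prompt or (n % 3 == 0),
        )
    elif button == Button.AMIODARONE:
        state = replace(state, amiodarone_prompt=False)
    elif button == Button.HDM_ROSC_TOGGLE:
        flipped = (
            CompressionsMode.ROSC
            if state.compressions_mode == CompressionsMode.CPR
            else CompressionsMode.CPR
        )
        state = replace(state, compressions_mode=flipped)
    # OTHER_INTERVENTION_* and HS_TS_EXPAND only log the interaction.
    return _recompute_alerts(state, config), record


def adrenaline_alert_rule(
    t_adrenaline: float, config: AidConfig = DEFAULT_CONFIG
) -> AdrenalineAlert:
    """Orange once the redosing window opens (>= 180 s since last dose)."""
    if t_adrenaline is None:
        raise ValueError("adrenaline timer not running (no dose documented)")
    if t_adrenaline >= config.adrenaline_consider_s:
        return AdrenalineAlert.CONSIDER
    return AdrenalineAlert.NONE


def interactions_per_minute(records: Sequence[InteractionRecord], duration: float) -> float:
    """Physical interactions with the app per minute of scenario."""
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return len(records) / (duration / 60.0)
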