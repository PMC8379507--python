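import numpy as np
import pytest

from cpraid.event_model import Event, EventKind, EventLog, Group


def make_log(
    events,
    team_id="T1",
    group=Group.CA_APP,
    arrival=0.0,
    end=900.0,
    rosc=None,
    excluded=False,
    reason="",
):
    return EventLog(
        team_id=team_id,
        group=group,
        arrival_time=arrival,
        scenario_end=end,
        events=tuple(Event(EventKind(k), t) for k, t in events),
        excluded=excluded,
        exclusion_reason=reason,
        rosc_time=rosc,
    )


@pytest.fixture
def simple_log():
    """A short, fully valid log: arrival 10 s, compressions with one
    rhythm-check pause, one shock, one adrenaline dose."""
    return make_log(
        [
            ("COMPRESSIONS_START", 20.0),
            ("COMPRESSIONS_STOP", 130.0),
            ("RHYTHM_CHECK_START", 130.0),
            ("RHYTHM_CHECK_END", 138.0),
            ("DEFIBRILLATION", 142.0),
            ("COMPRESSIONS_START", 145.0),
            ("ADRENALINE", 200.0),
            ("COMPRESSOR_CHANGE", 250.0),
            ("COMPRESSIONS_STOP", 300.0),
        ],
        arrival=10.0,
        end=300.0,
    )


def random_valid_log(rng: np.random.Generator):
    """Generate a structurally valid random log for property tests."""
    arrival = float(rng.uniform(0, 30))
    end = arrival + float(rng.uniform(200, 1200))
    events = []
    # alternating compression segments
    t = arrival + float(rng.uniform(0, 30))
    while t < end - 5:
        seg = float(rng.uniform(10, 150))
        stop = min(t + seg, end)
        events.append(("COMPRESSIONS_START", t))
        events.append(("COMPRESSIONS_STOP", stop))
        t = stop + float(rng.uniform(2, 40))
    # rhythm checks as disjoint intervals
    t = arrival + float(rng.uniform(30, 150))
    while t < end - 20:
        dur = float(rng.uniform(3, 12))
        events.append(("RHYTHM_CHECK_START", t))
        events.append(("RHYTHM_CHECK_END", t + dur))
        t += float(rng.uniform(100, 240))
    for kind, lam in [("DEFIBRILLATION", 4), ("ADRENALINE", 3), ("COMPRESSOR_CHANGE", 4)]:
        for _ in range(int(rng.poisson(lam))):
            events.append((kind, float(rng.uniform(arrival, end))))
    if rng.random() < 0.2:
        events.append(("AMIODARONE", float(rng.uniform(arrival, end))))
    events.sort(key=lambda e: e[1])
    rosc = float(rng.uniform(arrival + 100, end)) if rng.random() < 0.15 else None
    return make_log(events, arrival=arrival, end=end, rosc=rosc)
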