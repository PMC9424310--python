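"""Shared fixtures: a handcrafted 12-trial event log with hand-derived
labels, and session-scoped simulated subjects reused across test modules."""

from __future__ import annotations

from datetime import datetime

import pytest

from switchtask.events import (
    Event,
    EventCode,
    Location,
    Outcome,
    SubjectTimeline,
    build_trials,
)
from switchtask.simulate import MouseConfig, TaskConfig, simulate_subject

SESSION_START = datetime(2022, 3, 1, 7, 0, 0)


def handcrafted_events() -> list[Event]:
    """Twelve trials covering every outcome class.

    Trial plan (t0 in ms; signal 3000 = SHORT/left, 9000 = LONG/right):

    ==  =========  ======  =======================================  ================
    #   t0         signal  response events                          expected outcome
    ==  =========  ======  =======================================  ================
    1   0          3000    LEFT in 3500 (pellet 3600)               CORRECT_REWARDED
    2   100000     3000    LEFT in 104000, no pellet                CORRECT_PROBE
    3   200000     3000    RIGHT in 204000                          TIMING_ERROR
    4   300000     3000    only a pre-signal-end LEFT poke          TIME_OUT
    5   400000     9000    LEFT out 405800, RIGHT in 409200+pellet  CORRECT_REWARDED
    6   500000     9000    LEFT out 506000, RIGHT in 509100         CORRECT_PROBE
    7   600000     9000    re-pokes LEFT at 609300 (censored)       TIMING_ERROR
    8   700000     9000    only a pre-signal-end LEFT poke          TIME_OUT
    9   800000     3000    pre-signal RIGHT poke, LEFT in 803100    CORRECT_REWARDED
    10  900000     9000    pre-signal RIGHT poke, LEFT in 909050    TIMING_ERROR
    11  1000000    3000    LEFT in 1029000 (29 s), no pellet        CORRECT_PROBE
    12  1100000    3000    RIGHT in 1104000 first, LEFT in 1105000  TIMING_ERROR
    ==  =========  ======  =======================================  ================
    """
    raw: list[tuple[int, EventCode, Location]] = []

    def trial(t0, sig_ms, pokes, pellet_ms=None, pellet_loc=Location.RIGHT, end=None):
        raw.append((t0, EventCode.TRIAL_INIT, Location.CENTER))
        raw.append((t0, EventCode.LIGHT_ON, Location.CENTER))
        raw.append((t0 + sig_ms, EventCode.LIGHT_OFF, Location.CENTER))
        for loc, t_in, t_out in pokes:
            raw.append((t_in, EventCode.NOSE_IN, loc))
            raw.append((t_out, EventCode.NOSE_OUT, loc))
        if pellet_ms is not None:
            raw.append((pellet_ms, EventCode.PELLET, pellet_loc))
        raw.append((end, EventCode.TRIAL_END, Location.NONE))

    L, R = Location.LEFT, Location.RIGHT
    trial(0, 3000, [(L, 3500, 3900)], pellet_ms=3600, pellet_loc=L, end=5000)
    trial(100_000, 3000, [(L, 104_000, 104_400)], end=110_000)
    trial(200_000, 3000, [(R, 204_000, 204_300)], end=205_000)
    trial(300_000, 3000, [(L, 301_000, 301_500)], end=330_000)
    trial(400_000, 9000,
          [(L, 400_500, 401_000), (L, 401_500, 405_800), (R, 409_200, 409_700)],
          pellet_ms=409_300, pellet_loc=R, end=410_000)
    trial(500_000, 9000, [(L, 500_400, 506_000), (R, 509_100, 509_500)], end=510_000)
    trial(600_000, 9000, [(L, 600_500, 608_900), (L, 609_300, 609_800)], end=610_000)
    trial(700_000, 9000, [(L, 701_000, 702_000)], end=730_000)
    trial(800_000, 3000, [(R, 801_000, 801_400), (L, 803_100, 803_600)],
          pellet_ms=803_200, pellet_loc=L, end=804_000)
    trial(900_000, 9000, [(R, 905_000, 905_400), (L, 909_050, 909_450)], end=910_000)
    trial(1_000_000, 3000, [(L, 1_029_000, 1_029_500)], end=1_030_000)
    trial(1_100_000, 3000, [(R, 1_104_000, 1_104_200), (L, 1_105_000, 1_105_300)],
          end=1_106_000)

    raw.sort(key=lambda e: e[0])  # stable: ties keep emit order
    return [Event(timestamp_ms=t, code=c, location=loc) for t, c, loc in raw]


HANDCRAFTED_OUTCOMES = [
    Outcome.CORRECT_REWARDED,
    Outcome.CORRECT_PROBE,
    Outcome.TIMING_ERROR,
    Outcome.TIME_OUT,
    Outcome.CORRECT_REWARDED,
    Outcome.CORRECT_PROBE,
    Outcome.TIMING_ERROR,
    Outcome.TIME_OUT,
    Outcome.CORRECT_REWARDED,
    Outcome.TIMING_ERROR,
    Outcome.CORRECT_PROBE,
    Outcome.TIMING_ERROR,
]


@pytest.fixture()
def handcrafted_timeline() -> SubjectTimeline:
    events = handcrafted_events()
    tl = SubjectTimeline(
        subject_id="hand",
        group="WT",
        week=2,
        events=events,
        trials=[],
        session_start_clock=SESSION_START,
    )
    tl.trials = build_trials(events, probe_enabled=True)
    return tl


@pytest.fixture(scope="session")
def sim_week2():
    """One simulated week-2 subject (3 days) with its generating truth."""
    task = TaskConfig.for_week(2, session_days=3)
    mouse = MouseConfig(seed=11)
    return simulate_subject(task, mouse, subject_id="s11", group="WT", return_truth=True)


@pytest.fixture(scope="session")
def sim_week1():
    """One simulated week-1 subject (2 days)."""
    task = TaskConfig.for_week(1, session_days=2)
    mouse = MouseConfig(seed=5)
    return simulate_subject(task, mouse, subject_id="s5", group="KO")
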