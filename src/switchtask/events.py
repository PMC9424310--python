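"""Event-stream data model, event-log I/O and trial classification.

The home-cage operant device emits one timestamped row per event (light
on/off, nose in/out, pellet delivery, trial markers) with millisecond
resolution.  This module defines the in-memory containers (:class:`Event`,
:class:`TrialRecord`, :class:`SubjectTimeline`), reads and writes the CSV
event-log dialect, and segments a validated event stream into classified
trials.

Task structure
--------------
A trial is self-initiated at the centre hopper.  A light signal of 3 s
(short) or 9 s (long) then cues which lateral hopper will be rewarded:
left for short, right for long.  The first nose-poke at a lateral hopper
at or after the end of the signal resolves the trial — at the matching
hopper it is correct (rewarded, or unrewarded on probe trials), at the
other hopper it is a timing error.  If no lateral poke occurs within 30 s
of initiation the trial is a time-out.  Pokes made while the signal is
still on never resolve a trial; they are the normal "wait at the short
hopper, then switch" strategy and are retained in ``TrialRecord.pokes``
for the timing analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Sequence

import pandas as pd

__all__ = [
    "EventCode",
    "Location",
    "TrialType",
    "Outcome",
    "Event",
    "TrialRecord",
    "SubjectTimeline",
    "EventLogError",
    "ValidationError",
    "read_event_log",
    "write_event_log",
    "build_trials",
    "trials_to_frame",
]

#: Signal durations and trial timing constants (seconds).
T_SHORT_S = 3.0
T_LONG_S = 9.0
TIMEOUT_S = 30.0
ITI_FIXED_S = 30.0

#: Wall-clock light schedule (hours), 12:12 LD cycle.
LIGHT_ON_CLOCK = 7.0
LIGHT_OFF_CLOCK = 19.0


class EventCode(str, Enum):
    TRIAL_INIT = "TRIAL_INIT"
    LIGHT_ON = "LIGHT_ON"
    LIGHT_OFF = "LIGHT_OFF"
    NOSE_IN = "NOSE_IN"
    NOSE_OUT = "NOSE_OUT"
    PELLET = "PELLET"
    TRIAL_END = "TRIAL_END"
    HOUSE_LIGHT_ON = "HOUSE_LIGHT_ON"
    HOUSE_LIGHT_OFF = "HOUSE_LIGHT_OFF"


class Location(str, Enum):
    CENTER = "CENTER"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NONE = "NONE"


class TrialType(str, Enum):
    SHORT = "SHORT"
    LONG = "LONG"


class Outcome(str, Enum):
    CORRECT_REWARDED = "CORRECT_REWARDED"
    CORRECT_PROBE = "CORRECT_PROBE"
    TIMING_ERROR = "TIMING_ERROR"
    TIME_OUT = "TIME_OUT"


#: Hopper associated with each trial type (left <-> short, right <-> long).
HOPPER_FOR_TYPE = {TrialType.SHORT: Location.LEFT, TrialType.LONG: Location.RIGHT}
SIGNAL_MS_FOR_TYPE = {TrialType.SHORT: int(T_SHORT_S * 1000), TrialType.LONG: int(T_LONG_S * 1000)}
TYPE_FOR_SIGNAL_MS = {v: k for k, v in SIGNAL_MS_FOR_TYPE.items()}


class EventLogError(Exception):
    """Malformed event-log file (parse-level problem)."""


class ValidationError(Exception):
    """Structurally parseable log that violates a task invariant."""


@dataclass(frozen=True)
class Event:
    timestamp_ms: int
    code: EventCode
    location: Location


@dataclass
class TrialRecord:
    index: int
    start_ms: int
    trial_type: TrialType
    is_probe: bool
    signal_s: float
    outcome: Outcome
    response_ms: int
    reaction_time_s: float  # NaN when undefined
    switch_latency_s: float  # NaN when undefined; filled by timing analysis
    iti_s: float  # observed end -> next init; NaN for last trial
    pokes: list[tuple[Location, int, int]] = field(default_factory=list)

    @property
    def is_correct(self) -> bool:
        return self.outcome in (Outcome.CORRECT_REWARDED, Outcome.CORRECT_PROBE)


@dataclass
class SubjectTimeline:
    subject_id: str
    group: str
    week: int
    events: list[Event]
    trials: list[TrialRecord]
    session_start_clock: datetime
    light_on_clock: float = LIGHT_ON_CLOCK
    light_off_clock: float = LIGHT_OFF_CLOCK

    # -- circadian bookkeeping -------------------------------------------------

    def clock_hours(self, timestamp_ms: int) -> float:
        """Wall-clock hour of day (0-24) at the given session timestamp."""
        t = self.session_start_clock + timedelta(milliseconds=int(timestamp_ms))
        return t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9

    def hours_since_light_on(self, timestamp_ms: int) -> float:
        """Hours elapsed since the most recent light onset (07:00)."""
        return (self.clock_hours(timestamp_ms) - self.light_on_clock) % 24.0

    def circadian_day(self, timestamp_ms: int) -> int:
        """Day index with day boundaries aligned to light onset, day 0 holding
        the session start."""
        start_offset = (
            self.session_start_clock.hour
            + self.session_start_clock.minute / 60
            + self.session_start_clock.second / 3600
            - self.light_on_clock
        ) % 24.0
        total_h = start_offset + timestamp_ms / 3.6e6
        return int(math.floor(total_h / 24.0))

    def hours_to_light_off(self, timestamp_ms: int) -> float:
        """Signed hours relative to the nearest light-off transition,
        negative before light-off.  Used by the improvement-curve analysis
        (window -10 h .. +12 h around light-off)."""
        rel = self.hours_since_light_on(timestamp_ms) - (
            (self.light_off_clock - self.light_on_clock) % 24.0
        )
        # fold into [-12, 12)
        return (rel + 12.0) % 24.0 - 12.0


# ---------------------------------------------------------------------------
# Event-log CSV dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("subject_id", "group", "week", "session_start_clock")

_VALID_CODES = {c.value for c in EventCode}
_VALID_LOCS = {l.value for l in Location}


def write_event_log(timeline: SubjectTimeline, path) -> None:
    """Write a timeline's events to the CSV event-log dialect.

    Four ``#``-prefixed header lines carry the subject metadata, followed by
    a ``timestamp_ms,code,location`` table.  The file round-trips losslessly
    through :func:`read_event_log`.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject_id: {timeline.subject_id}\n")
        fh.write(f"# group: {timeline.group}\n")
        fh.write(f"# week: {timeline.week}\n")
        fh.write(f"# session_start_clock: {timeline.session_start_clock.isoformat()}\n")
        fh.write("timestamp_ms,code,location\n")
        for ev in timeline.events:
            fh.write(f"{ev.timestamp_ms},{ev.code.value},{ev.location.value}\n")


def read_event_log(path, probe_enabled: bool | None = None) -> SubjectTimeline:
    """Read an event-log CSV and build classified trials.

    Parameters
    ----------
    path
        Path to a log written by :func:`write_event_log` (or by the
        acquisition system in the same dialect).
    probe_enabled
        Whether unrewarded probe trials are possible.  Defaults to
        ``week == 2`` from the file header.

    Raises
    ------
    EventLogError
        Malformed header or data row (the message names the line number).
    ValidationError
        Non-monotone timestamps, unknown codes, or task-rule violations.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if ":" not in body:
            raise EventLogError(f"line {n_header}: malformed header line {line!r}")
        key, _, value = body.partition(":")
        meta[key.strip()] = value.strip()
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise EventLogError(f"header missing keys: {missing}")

    events: list[Event] = []
    prev_ts = None
    for lineno, line in enumerate(lines[n_header:], start=n_header + 1):
        line = line.strip()
        if not line:
            continue
        if lineno == n_header + 1:
            if line != "timestamp_ms,code,location":
                raise EventLogError(f"line {lineno}: expected column header, got {line!r}")
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise EventLogError(f"line {lineno}: expected 3 fields, got {len(parts)}")
        ts_s, code, loc = parts
        try:
            ts = int(ts_s)
        except ValueError:
            raise EventLogError(f"line {lineno}: bad timestamp {ts_s!r}") from None
        if code not in _VALID_CODES:
            raise ValidationError(f"line {lineno}: unknown event code {code!r}")
        if loc not in _VALID_LOCS:
            raise ValidationError(f"line {lineno}: unknown location {loc!r}")
        if prev_ts is not None and ts < prev_ts:
            raise ValidationError(f"line {lineno}: timestamps not non-decreasing")
        prev_ts = ts
        events.append(Event(ts, EventCode(code), Location(loc)))

    week = int(meta["week"])
    timeline = SubjectTimeline(
        subject_id=meta["subject_id"],
        group=meta["group"],
        week=week,
        events=events,
        trials=[],
        session_start_clock=datetime.fromisoformat(meta["session_start_clock"]),
    )
    if probe_enabled is None:
        probe_enabled = week == 2
    timeline.trials = build_trials(events, probe_enabled=probe_enabled)
    return timeline


# ---------------------------------------------------------------------------
# Trial segmentation and classification
# ---------------------------------------------------------------------------


def _validate_poke_pairing(events: Sequence[Event]) -> None:
    open_pokes: dict[Location, int] = {}
    for ev in events:
        if ev.code is EventCode.NOSE_IN:
            if ev.location in open_pokes:
                raise ValidationError(
                    f"NOSE_IN at {ev.location.value} at {ev.timestamp_ms} ms while previous "
                    "poke at that location is still open"
                )
            open_pokes[ev.location] = ev.timestamp_ms
        elif ev.code is EventCode.NOSE_OUT:
            if ev.location not in open_pokes:
                raise ValidationError(
                    f"NOSE_OUT at {ev.location.value} at {ev.timestamp_ms} ms without a "
                    "matching NOSE_IN"
                )
            del open_pokes[ev.location]


def build_trials(events: Sequence[Event], probe_enabled: bool) -> list[TrialRecord]:
    """Segment a validated event stream into classified :class:`TrialRecord`.

    Every ``TRIAL_INIT`` opens a trial that runs to the matching
    ``TRIAL_END``.  The signal duration is taken from the centre-hopper
    ``LIGHT_ON``/``LIGHT_OFF`` pair and must be 3 or 9 s.  Classification:

    * first lateral ``NOSE_IN`` at or after signal end at the matching
      hopper -> ``CORRECT_REWARDED`` if a ``PELLET`` follows within the
      trial, else ``CORRECT_PROBE`` (only when ``probe_enabled``);
    * first lateral ``NOSE_IN`` at or after signal end at the other
      hopper -> ``TIMING_ERROR``;
    * no lateral poke at or after signal end within 30 s -> ``TIME_OUT``
      with ``response_ms`` exactly 30 000 ms after initiation.

    A ``TRIAL_INIT`` within the 30 s fixed ITI lockout after the previous
    ``TRIAL_END`` raises :class:`ValidationError` (the task forbids
    initiations during the ITI; only the fixed part of the ITI is
    verifiable from the log).
    """
    _validate_poke_pairing(events)

    trials: list[TrialRecord] = []
    i = 0
    n = len(events)
    prev_end_ms: int | None = None
    timeout_ms = int(TIMEOUT_S * 1000)
    while i < n:
        ev = events[i]
        if ev.code is not EventCode.TRIAL_INIT:
            i += 1
            continue
        start_ms = ev.timestamp_ms
        if prev_end_ms is not None and start_ms - prev_end_ms < int(ITI_FIXED_S * 1000):
            raise ValidationError(
                f"TRIAL_INIT at {start_ms} ms falls inside the inter-trial interval "
                f"({start_ms - prev_end_ms} ms after the previous TRIAL_END)"
            )
        # collect this trial's events
        j = i + 1
        trial_events: list[Event] = []
        end_ms: int | None = None
        while j < n:
            e = events[j]
            if e.code is EventCode.TRIAL_END:
                end_ms = e.timestamp_ms
                break
            if e.code is EventCode.TRIAL_INIT:
                raise ValidationError(
                    f"TRIAL_INIT at {e.timestamp_ms} ms before the trial starting at "
                    f"{start_ms} ms has ended"
                )
            trial_events.append(e)
            j += 1
        if end_ms is None:
            raise ValidationError(f"trial starting at {start_ms} ms has no TRIAL_END")

        trials.append(
            _classify_trial(
                len(trials), start_ms, end_ms, trial_events, probe_enabled, timeout_ms
            )
        )
        prev_end_ms = end_ms
        i = j + 1

    _fill_observed_iti(trials, events)
    return trials


def _fill_observed_iti(trials: list[TrialRecord], events: Sequence[Event]) -> None:
    ends = [ev.timestamp_ms for ev in events if ev.code is EventCode.TRIAL_END]
    inits = [ev.timestamp_ms for ev in events if ev.code is EventCode.TRIAL_INIT]
    for k, tr in enumerate(trials):
        if k + 1 < len(trials):
            tr.iti_s = (inits[k + 1] - ends[k]) / 1000.0
        else:
            tr.iti_s = float("nan")


def _classify_trial(
    index: int,
    start_ms: int,
    end_ms: int,
    trial_events: Sequence[Event],
    probe_enabled: bool,
    timeout_ms: int,
) -> TrialRecord:
    # signal duration from the centre light pair
    light_on = [e for e in trial_events if e.code is EventCode.LIGHT_ON]
    light_off = [e for e in trial_events if e.code is EventCode.LIGHT_OFF]
    if not light_on or not light_off:
        raise ValidationError(f"trial at {start_ms} ms lacks a LIGHT_ON/LIGHT_OFF signal pair")
    signal_ms = light_off[0].timestamp_ms - light_on[0].timestamp_ms
    if signal_ms not in TYPE_FOR_SIGNAL_MS:
        raise ValidationError(
            f"trial at {start_ms} ms has signal duration {signal_ms} ms (expected 3000 or 9000)"
        )
    trial_type = TYPE_FOR_SIGNAL_MS[signal_ms]
    signal_end_ms = light_on[0].timestamp_ms + signal_ms

    pokes = _poke_intervals(trial_events, end_ms)
    has_pellet = any(e.code is EventCode.PELLET for e in trial_events)

    resolving = None
    for e in trial_events:
        if (
            e.code is EventCode.NOSE_IN
            and e.location in (Location.LEFT, Location.RIGHT)
            and e.timestamp_ms >= signal_end_ms
        ):
            resolving = e
            break

    correct_hopper = HOPPER_FOR_TYPE[trial_type]
    if resolving is None:
        outcome = Outcome.TIME_OUT
        response_ms = start_ms + timeout_ms
        reaction_s = float("nan")
    else:
        response_ms = resolving.timestamp_ms
        if resolving.location is correct_hopper:
            if has_pellet:
                outcome = Outcome.CORRECT_REWARDED
            elif probe_enabled:
                outcome = Outcome.CORRECT_PROBE
            else:
                raise ValidationError(
                    f"trial at {start_ms} ms: correct response without pellet in a "
                    "probe-free session"
                )
        else:
            outcome = Outcome.TIMING_ERROR
        # reaction time: first poke at the type-associated hopper after signal end
        reaction_s = float("nan")
        for e in trial_events:
            if (
                e.code is EventCode.NOSE_IN
                and e.location is correct_hopper
                and e.timestamp_ms >= signal_end_ms
            ):
                reaction_s = (e.timestamp_ms - signal_end_ms) / 1000.0
                break

    return TrialRecord(
        index=index,
        start_ms=start_ms,
        trial_type=trial_type,
        is_probe=outcome is Outcome.CORRECT_PROBE,
        signal_s=signal_ms / 1000.0,
        outcome=outcome,
        response_ms=response_ms,
        reaction_time_s=reaction_s,
        switch_latency_s=float("nan"),
        iti_s=float("nan"),
        pokes=pokes,
    )


def _poke_intervals(trial_events: Sequence[Event], end_ms: int) -> list[tuple[Location, int, int]]:
    open_pokes: dict[Location, int] = {}
    out: list[tuple[Location, int, int]] = []
    for e in trial_events:
        if e.code is EventCode.NOSE_IN:
            open_pokes[e.location] = e.timestamp_ms
        elif e.code is EventCode.NOSE_OUT and e.location in open_pokes:
            out.append((e.location, open_pokes.pop(e.location), e.timestamp_ms))
    for loc, t_in in open_pokes.items():  # poke still open at trial end
        out.append((loc, t_in, end_ms))
    out.sort(key=lambda p: p[1])
    return out


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def trials_to_frame(timeline: SubjectTimeline) -> pd.DataFrame:
    """Flatten classified trials into a tidy DataFrame (one row per trial).

    Adds the circadian columns used downstream: ``day`` (light-onset
    aligned), ``hour`` (hours since light onset, 0-24) and
    ``hours_to_light_off``.
    """
    rows = []
    for tr in timeline.trials:
        rows.append(
            {
                "subject_id": timeline.subject_id,
                "group": timeline.group,
                "week": timeline.week,
                "index": tr.index,
                "start_ms": tr.start_ms,
                "trial_type": tr.trial_type.value,
                "is_probe": tr.is_probe,
                "signal_s": tr.signal_s,
                "outcome": tr.outcome.value,
                "response_ms": tr.response_ms,
                "reaction_time_s": tr.reaction_time_s,
                "iti_s": tr.iti_s,
                "day": timeline.circadian_day(tr.start_ms),
                "hour": timeline.hours_since_light_on(tr.start_ms),
                "hours_to_light_off": timeline.hours_to_light_off(tr.start_ms),
                "correct": tr.is_correct,
            }
        )
    cols = [
        "subject_id", "group", "week", "index", "start_ms", "trial_type", "is_probe",
        "signal_s", "outcome", "response_ms", "reaction_time_s", "iti_s", "day",
        "hour", "hours_to_light_off", "correct",
    ]
    return pd.DataFrame(rows, columns=cols)
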