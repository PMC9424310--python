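"""Synthetic-mouse simulator for the switch task.

Two layers are simulated with known ground truth so that every downstream
analysis stage can be validated by parameter recovery:

* the **scheduler** (:func:`schedule_trial`), which draws the trial type
  (short/long with equal probability), the probe flag (20 % conditional
  probability in week 2) and the inter-trial interval (30 s fixed plus a
  geometric random part with mean 60 s);
* the **subject** (:func:`simulate_subject`), a generative decision model
  in which each engaged trial carries one planned switch latency
  ``t_sw ~ Normal(mu, cv * mu)``.  A short trial is correct iff
  ``t_sw > T_S`` (the animal is still at the short hopper when the 3 s
  signal ends) and a long trial is correct iff ``t_sw < T_L`` (it has
  switched before the 9 s signal ends); planned switches past ``T_L`` are
  censored — the animal never leaves the short hopper and the trial
  resolves as a timing error there.  Time-outs (disengaged trials) are
  drawn with a light/dark-phase-specific lapse probability, trial
  initiations follow a thinned Poisson process whose rate is modulated by
  a sinusoid of configurable period, and the timing-error probability
  steps from a pre- to a post-learning value at a configurable trial
  index.

The emitted event stream obeys the task rules bit-exactly (3/9 s signals,
30 s time-out, ITI lockout, unrewarded probes) and is deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .events import (
    Event,
    EventCode,
    Location,
    SubjectTimeline,
    TrialType,
    build_trials,
)

__all__ = ["TaskConfig", "MouseConfig", "ConfigError", "ScheduledTrial", "schedule_trial", "simulate_subject"]


class ConfigError(ValueError):
    """Inconsistent task or subject configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Task scheduler parameters (the published task constants)."""

    t_short_s: float = 3.0
    t_long_s: float = 9.0
    p_short: float = 0.5
    p_probe: float = 0.0  # 0.2 in week 2
    timeout_s: float = 30.0
    iti_fixed_s: float = 30.0
    iti_geometric_mean_s: float = 60.0
    light_on_clock: float = 7.0
    light_off_clock: float = 19.0
    session_days: int = 7
    session_start_clock: datetime = datetime(2022, 3, 1, 7, 0, 0)

    def __post_init__(self):
        if not (0.0 <= self.p_short <= 1.0 and 0.0 <= self.p_probe <= 1.0):
            raise ConfigError("p_short and p_probe must lie in [0, 1]")
        if not self.t_short_s < self.t_long_s:
            raise ConfigError("t_short_s must be smaller than t_long_s")
        if self.session_days < 1:
            raise ConfigError("session_days must be >= 1")

    @classmethod
    def for_week(cls, week: int, **kwargs) -> "TaskConfig":
        """Standard configuration for training week 1 (no probes) or
        week 2 (20 % probe trials)."""
        if week not in (1, 2):
            raise ConfigError("week must be 1 or 2")
        return cls(p_probe=0.2 if week == 2 else 0.0, **kwargs)


@dataclass(frozen=True)
class MouseConfig:
    """Generative subject parameters (ground truth for recovery tests).

    ``mu_s`` and ``cv`` parameterise the planned switch latency
    (timing accuracy and uncertainty); ``p_timeout_*`` are per-phase lapse
    probabilities; ``init_rate_*`` per-phase trial-initiation rates in
    trials/hour; the sinusoidal activity modulation has amplitude
    ``circadian_amplitude`` (relative), period ``period_h`` hours and phase
    ``phase_rad``; the timing-error probability steps from ``p_err_pre`` to
    ``p_err_post`` at trial index ``learning_trial_true``.
    """

    mu_s: float = 6.0
    cv: float = 0.15
    p_timeout_light: float = 0.25
    p_timeout_dark: float = 0.08
    init_rate_light: float = 5.0
    init_rate_dark: float = 15.0
    circadian_amplitude: float = 0.6
    period_h: float = 24.0
    phase_rad: float = -math.pi  # activity peak mid-dark-phase for a 24 h period
    learning_trial_true: int = 150
    p_err_pre: float = 0.5
    p_err_post: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.cv <= 0:
            raise ConfigError("cv must be positive")
        if not (21.0 <= self.period_h <= 27.0):
            raise ConfigError("period_h must lie in [21, 27] h")
        for name in ("p_timeout_light", "p_timeout_dark", "p_err_pre", "p_err_post"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.init_rate_light < 0 or self.init_rate_dark < 0:
            raise ConfigError("initiation rates must be non-negative")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ConfigError("circadian_amplitude must lie in [0, 1]")


class ScheduledTrial(NamedTuple):
    trial_type: TrialType
    is_probe: bool
    iti_s: float


def schedule_trial(rng: np.random.Generator, cfg: TaskConfig) -> ScheduledTrial:
    """Draw one trial's schedule: type, probe flag and following ITI.

    The trial is short with probability ``p_short``; the probe flag is
    drawn conditionally on the type with probability ``p_probe``; the ITI
    is the fixed delay plus an integer-second geometric random part on
    {0, 1, 2, ...} with the configured mean (success parameter
    ``1 / (mean + 1)``).
    """
    trial_type = TrialType.SHORT if rng.random() < cfg.p_short else TrialType.LONG
    is_probe = bool(cfg.p_probe > 0 and rng.random() < cfg.p_probe)
    p = 1.0 / (cfg.iti_geometric_mean_s + 1.0)
    iti_s = cfg.iti_fixed_s + float(rng.geometric(p) - 1)
    return ScheduledTrial(trial_type, is_probe, iti_s)


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------


def _clock_hours(cfg: TaskConfig, t_s: float) -> float:
    start = cfg.session_start_clock
    h0 = start.hour + start.minute / 60 + start.second / 3600
    return (h0 + t_s / 3600.0) % 24.0

def _is_light(cfg: TaskConfig, t_s: float) -> bool:
    h = _clock_hours(cfg, t_s)
    on, off = cfg.light_on_clock, cfg.light_off_clock
    if on <= off:
        return on <= h < off
    return h >= on or h < off


def _init_rate_per_s(cfg: TaskConfig, mouse: MouseConfig, t_s: float) -> float:
    base = mouse.init_rate_light if _is_light(cfg, t_s) else mouse.init_rate_dark
    mod = mouse.circadian_amplitude * (
        math.sin(2.0 * math.pi * (t_s / 3600.0) / mouse.period_h + mouse.phase_rad) + 1.0
    ) / 2.0
    return base * (1.0 + mod) / 3600.0


def _draw_switch_time(
    rng: np.random.Generator, mouse: MouseConfig, trial_type: TrialType, is_error: bool,
    t_short: float, t_long: float,
) -> float:
    """Planned switch latency conditioned on the intended outcome class."""
    mu, sigma = mouse.mu_s, mouse.cv * mouse.mu_s
    lo_travel = 0.3  # cannot express a switch faster than hopper travel
    if trial_type is TrialType.SHORT:
        lo, hi = (t_short, mu + 8 * sigma) if not is_error else (lo_travel, t_short)
    else:
        lo, hi = (lo_travel, t_long) if not is_error else (t_long, t_long + 8 * sigma)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))


def _poke_bouts(
    rng: np.random.Generator, start: float, end: float, anchor_end: bool = False
) -> list[tuple[float, float]]:
    """Repeated nose-poke (in, out) intervals filling [start, end).

    In-times stay strictly below ``end``.  With ``anchor_end`` the final
    out-time is placed exactly at ``end`` (used to make the planned switch
    latency the literal last short-hopper NOSE_OUT on long trials).
    """
    bouts: list[tuple[float, float]] = []
    t = start
    while t + 0.05 < end:
        dur = rng.uniform(0.2, 0.6)
        out = min(t + dur, end)
        bouts.append((t, out))
        t = out + rng.uniform(0.15, 0.7)
    if anchor_end and bouts:
        t_in, _ = bouts[-1]
        bouts[-1] = (t_in, end)
    return bouts


def simulate_subject(
    task: TaskConfig,
    mouse: MouseConfig,
    subject_id: str = "sim",
    group: str = "WT",
    week: int | None = None,
    return_truth: bool = False,
):
    """Simulate one subject's full event stream.

    Returns the classified :class:`~switchtask.events.SubjectTimeline`
    (and, with ``return_truth``, a per-trial DataFrame of the generating
    ground truth: intended outcome class, planned switch time, engagement,
    scheduled ITI).
    """
    if mouse.mu_s <= 0 or mouse.mu_s >= task.timeout_s:
        raise ConfigError("mu_s must lie in (0, timeout_s)")
    if mouse.mu_s + 8 * mouse.cv * mouse.mu_s >= task.timeout_s:
        raise ConfigError("switch-latency distribution extends past the time-out window")
    if week is None:
        week = 2 if task.p_probe > 0 else 1

    rng = np.random.default_rng(mouse.seed)
    session_end_s = task.session_days * 86400.0
    lam_max = max(mouse.init_rate_light, mouse.init_rate_dark) * (1.0 + mouse.circadian_amplitude) / 3600.0

    raw: list[tuple[float, EventCode, Location]] = []
    truth_rows: list[dict] = []

    # house-light transitions over the session
    _emit_house_lights(task, session_end_s, raw)

    t = 0.0
    trial_idx = 0
    while True:
        # next initiation: thinned Poisson from the current lockout-free time
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t + task.timeout_s + 5.0 > session_end_s:
                t = math.inf
                break
            if rng.random() < _init_rate_per_s(task, mouse, t) / lam_max:
                break
        if not math.isfinite(t):
            break

        sched = schedule_trial(rng, task)
        p_err = mouse.p_err_pre if trial_idx < mouse.learning_trial_true else mouse.p_err_post
        p_to = mouse.p_timeout_light if _is_light(task, t) else mouse.p_timeout_dark
        engaged = rng.random() >= p_to

        end_s = _emit_trial(rng, raw, task, mouse, t, sched, engaged, p_err, truth_rows, trial_idx)
        t = end_s + sched.iti_s
        trial_idx += 1

    events = _finalize_events(raw)
    timeline = SubjectTimeline(
        subject_id=subject_id,
        group=group,
        week=week,
        events=events,
        trials=[],
        session_start_clock=task.session_start_clock,
        light_on_clock=task.light_on_clock,
        light_off_clock=task.light_off_clock,
    )
    timeline.trials = build_trials(events, probe_enabled=task.p_probe > 0)
    if return_truth:
        return timeline, pd.DataFrame(truth_rows)
    return timeline


def _emit_house_lights(task: TaskConfig, session_end_s: float, raw: list) -> None:
    start = task.session_start_clock
    h0 = start.hour + start.minute / 60 + start.second / 3600
    for clock, code in (
        (task.light_on_clock, EventCode.HOUSE_LIGHT_ON),
        (task.light_off_clock, EventCode.HOUSE_LIGHT_OFF),
    ):
        t = ((clock - h0) % 24.0) * 3600.0
        while t < session_end_s:
            if t > 0:
                raw.append((t, code, Location.NONE))
            t += 86400.0


def _emit_trial(
    rng: np.random.Generator,
    raw: list,
    task: TaskConfig,
    mouse: MouseConfig,
    t0: float,
    sched: ScheduledTrial,
    engaged: bool,
    p_err: float,
    truth_rows: list,
    trial_idx: int,
) -> float:
    """Emit one trial's events starting at ``t0`` seconds; return trial end time."""
    sig = task.t_short_s if sched.trial_type is TrialType.SHORT else task.t_long_s
    raw.append((t0, EventCode.TRIAL_INIT, Location.CENTER))
    raw.append((t0, EventCode.NOSE_IN, Location.CENTER))
    raw.append((t0 + 0.25, EventCode.NOSE_OUT, Location.CENTER))
    raw.append((t0, EventCode.LIGHT_ON, Location.CENTER))
    raw.append((t0 + sig, EventCode.LIGHT_OFF, Location.CENTER))

    if not engaged:
        end = t0 + task.timeout_s
        raw.append((end, EventCode.TRIAL_END, Location.NONE))
        truth_rows.append(
            dict(index=trial_idx, start_s=t0, trial_type=sched.trial_type.value,
                 is_probe=sched.is_probe, intended="TIME_OUT", t_sw=np.nan,
                 iti_scheduled_s=sched.iti_s)
        )
        return end

    is_error = rng.random() < p_err
    t_sw = _draw_switch_time(rng, mouse, sched.trial_type, is_error, task.t_short_s, task.t_long_s)
    travel = 0.3
    d = rng.uniform(0.15, 0.6)
    poke_start = t0 + rng.uniform(0.35, 0.8)
    long_trial = sched.trial_type is TrialType.LONG

    # hopper occupied when the signal ends determines the resolving poke
    at_left_at_sig = (t_sw >= task.t_long_s) if long_trial else (t_sw > task.t_short_s)
    resolving_loc = Location.LEFT if at_left_at_sig else Location.RIGHT
    arrival = t0 if at_left_at_sig else t0 + t_sw + travel
    t_res = max(t0 + sig, arrival) + d

    # short-hopper occupancy runs from trial start to the planned switch (or
    # to signal end when no switch is expressed before it); on long trials
    # with an expressed switch the final NOSE_OUT is anchored exactly at
    # t_sw, the quantity the latency extractor measures
    left_end = t0 + min(t_sw, sig)
    anchored = long_trial and not at_left_at_sig
    for t_in, t_out in _poke_bouts(rng, poke_start, left_end, anchor_end=anchored):
        raw.append((t_in, EventCode.NOSE_IN, Location.LEFT))
        raw.append((t_out, EventCode.NOSE_OUT, Location.LEFT))
    if not at_left_at_sig:
        # long-hopper occupancy between the switch and signal end never
        # resolves (pre-signal-end pokes are inert)
        for t_in, t_out in _poke_bouts(rng, t0 + t_sw + travel, t0 + sig):
            raw.append((t_in, EventCode.NOSE_IN, Location.RIGHT))
            raw.append((t_out, EventCode.NOSE_OUT, Location.RIGHT))

    # resolving poke
    res_dur = rng.uniform(0.3, 0.7)
    raw.append((t_res, EventCode.NOSE_IN, resolving_loc))
    raw.append((t_res + res_dur, EventCode.NOSE_OUT, resolving_loc))

    correct_loc = Location.LEFT if sched.trial_type is TrialType.SHORT else Location.RIGHT
    correct = resolving_loc is correct_loc
    rewarded = correct and not sched.is_probe
    if rewarded:
        raw.append((t_res + 0.05, EventCode.PELLET, correct_loc))

    if sched.is_probe:
        # probe trials run the full 30 s window; the animal plays out its plan
        end = t0 + task.timeout_s
        _emit_probe_persistence(rng, raw, t0, t_sw, t_res + res_dur, sig, task, long_trial)
        raw.append((end, EventCode.TRIAL_END, Location.NONE))
    else:
        end = t_res + res_dur + 0.25
        raw.append((end, EventCode.TRIAL_END, Location.NONE))

    intended = (
        ("CORRECT_PROBE" if sched.is_probe else "CORRECT_REWARDED")
        if correct
        else "TIMING_ERROR"
    )
    truth_rows.append(
        dict(index=trial_idx, start_s=t0, trial_type=sched.trial_type.value,
             is_probe=sched.is_probe, intended=intended, t_sw=t_sw,
             iti_scheduled_s=sched.iti_s)
    )
    return end


def _emit_probe_persistence(
    rng, raw, t0, t_sw, t_free, sig, task: TaskConfig, long_trial: bool
) -> None:
    """Continued (non-resolving) poking after an unrewarded probe response.

    On short probes the animal keeps working the short hopper until its
    planned switch time, then pokes the long hopper until shortly after the
    long target — the behaviour that makes probe occupancy reveal the
    planned switch latency.
    """
    limit = t0 + task.timeout_s - 0.5
    if not long_trial and t_sw > sig:
        # still at the short hopper: persist there until t_sw, then switch
        for t_in, t_out in _poke_bouts(rng, t_free + 0.2, min(t0 + t_sw, limit)):
            raw.append((t_in, EventCode.NOSE_IN, Location.LEFT))
            raw.append((t_out, EventCode.NOSE_OUT, Location.LEFT))
        give_up = min(t0 + task.t_long_s + rng.uniform(0.5, 2.0), limit)
        for t_in, t_out in _poke_bouts(rng, max(t0 + t_sw + 0.3, t_free + 0.2), give_up):
            raw.append((t_in, EventCode.NOSE_IN, Location.RIGHT))
            raw.append((t_out, EventCode.NOSE_OUT, Location.RIGHT))
    else:
        # already at the final hopper: brief persistence there
        loc = Location.RIGHT if (long_trial and t_sw < task.t_long_s) or (not long_trial and t_sw <= sig) else Location.LEFT
        give_up = min(t_free + rng.uniform(0.5, 2.0), limit)
        for t_in, t_out in _poke_bouts(rng, t_free + 0.2, give_up):
            raw.append((t_in, EventCode.NOSE_IN, loc))
            raw.append((t_out, EventCode.NOSE_OUT, loc))


def _finalize_events(raw: list[tuple[float, EventCode, Location]]) -> list[Event]:
    """Round to integer milliseconds and sort stably by time."""
    order = {
        EventCode.TRIAL_INIT: 0, EventCode.LIGHT_ON: 1, EventCode.NOSE_IN: 2,
        EventCode.NOSE_OUT: 3, EventCode.LIGHT_OFF: 4, EventCode.PELLET: 5,
        EventCode.TRIAL_END: 6, EventCode.HOUSE_LIGHT_ON: 2, EventCode.HOUSE_LIGHT_OFF: 2,
    }
    indexed = [
        (int(round(t * 1000.0)), i, order[code], code, loc)
        for i, (t, code, loc) in enumerate(raw)
    ]
    indexed.sort(key=lambda r: (r[0], r[1]))
    return [Event(ts, code, loc) for ts, _i, _o, code, loc in indexed]
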