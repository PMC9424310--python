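"""Event model, log round trip and trial classification."""

import math
from datetime import datetime

import pytest

from switchtask.events import (
    Event,
    EventCode,
    Location,
    Outcome,
    SubjectTimeline,
    TrialType,
    ValidationError,
    build_trials,
    read_event_log,
    trials_to_frame,
    write_event_log,
)

from conftest import HANDCRAFTED_OUTCOMES, SESSION_START, handcrafted_events


class TestHandcraftedClassification:
    def test_outcomes_exact(self, handcrafted_timeline):
        got = [tr.outcome for tr in handcrafted_timeline.trials]
        assert got == HANDCRAFTED_OUTCOMES

    def test_trial_types(self, handcrafted_timeline):
        types = [tr.trial_type for tr in handcrafted_timeline.trials]
        expected = [
            TrialType.SHORT, TrialType.SHORT, TrialType.SHORT, TrialType.SHORT,
            TrialType.LONG, TrialType.LONG, TrialType.LONG, TrialType.LONG,
            TrialType.SHORT, TrialType.LONG, TrialType.SHORT, TrialType.SHORT,
        ]
        assert types == expected

    def test_probe_flags(self, handcrafted_timeline):
        probes = [tr.is_probe for tr in handcrafted_timeline.trials]
        assert probes == [o is Outcome.CORRECT_PROBE for o in HANDCRAFTED_OUTCOMES]

    def test_reaction_times(self, handcrafted_timeline):
        trs = handcrafted_timeline.trials
        # first poke at the type-associated hopper after signal end
        assert trs[0].reaction_time_s == pytest.approx(0.5)
        assert trs[1].reaction_time_s == pytest.approx(1.0)
        assert math.isnan(trs[2].reaction_time_s)  # never poked left after 3 s
        assert trs[4].reaction_time_s == pytest.approx(0.2)
        assert trs[10].reaction_time_s == pytest.approx(26.0)
        assert trs[11].reaction_time_s == pytest.approx(2.0)  # left poke, after the error

    def test_timeout_response_is_30s(self, handcrafted_timeline):
        trs = handcrafted_timeline.trials
        for k in (3, 7):
            assert trs[k].outcome is Outcome.TIME_OUT
            assert trs[k].response_ms == trs[k].start_ms + 30_000
            assert math.isnan(trs[k].reaction_time_s)

    def test_pre_signal_pokes_are_inert(self, handcrafted_timeline):
        # trial 9: a RIGHT poke before signal end must not resolve the trial
        assert handcrafted_timeline.trials[8].outcome is Outcome.CORRECT_REWARDED

    def test_observed_iti(self, handcrafted_timeline):
        trs = handcrafted_timeline.trials
        assert trs[0].iti_s == pytest.approx(95.0)  # 100000 ms init - 5000 ms end
        assert math.isnan(trs[-1].iti_s)

    def test_partition_invariant(self, handcrafted_timeline):
        trs = handcrafted_timeline.trials
        n_correct = sum(tr.is_correct for tr in trs)
        n_te = sum(tr.outcome is Outcome.TIMING_ERROR for tr in trs)
        n_to = sum(tr.outcome is Outcome.TIME_OUT for tr in trs)
        assert n_correct + n_te + n_to == len(trs) == 12


class TestRoundTrip:
    def test_lossless(self, handcrafted_timeline, tmp_path):
        p = tmp_path / "hand.csv"
        write_event_log(handcrafted_timeline, p)
        back = read_event_log(p)
        assert back.subject_id == "hand"
        assert back.group == "WT"
        assert back.week == 2
        assert back.session_start_clock == SESSION_START
        assert back.events == handcrafted_timeline.events
        assert [t.outcome for t in back.trials] == HANDCRAFTED_OUTCOMES

    def test_simulated_round_trip(self, sim_week2, tmp_path):
        tl, _ = sim_week2
        p = tmp_path / "sim.csv"
        write_event_log(tl, p)
        back = read_event_log(p)
        assert back.events == tl.events
        assert [t.outcome for t in back.trials] == [t.outcome for t in tl.trials]


class TestValidation:
    def test_correct_without_pellet_rejected_in_probe_free_session(self):
        with pytest.raises(ValidationError, match="without pellet"):
            build_trials(handcrafted_events(), probe_enabled=False)

    def test_iti_lockout_violation(self):
        ev = [
            Event(0, EventCode.TRIAL_INIT, Location.CENTER),
            Event(0, EventCode.LIGHT_ON, Location.CENTER),
            Event(3000, EventCode.LIGHT_OFF, Location.CENTER),
            Event(30_000, EventCode.TRIAL_END, Location.NONE),
            Event(40_000, EventCode.TRIAL_INIT, Location.CENTER),  # 10 s < 30 s lockout
            Event(40_000, EventCode.LIGHT_ON, Location.CENTER),
            Event(43_000, EventCode.LIGHT_OFF, Location.CENTER),
            Event(70_000, EventCode.TRIAL_END, Location.NONE),
        ]
        with pytest.raises(ValidationError, match="inter-trial interval"):
            build_trials(ev, probe_enabled=True)

    def test_nested_trial_init(self):
        ev = [
            Event(0, EventCode.TRIAL_INIT, Location.CENTER),
            Event(1000, EventCode.TRIAL_INIT, Location.CENTER),
            Event(50_000, EventCode.TRIAL_END, Location.NONE),
        ]
        with pytest.raises(ValidationError, match="before the trial"):
            build_trials(ev, probe_enabled=True)

    def test_missing_trial_end(self):
        ev = [
            Event(0, EventCode.TRIAL_INIT, Location.CENTER),
            Event(0, EventCode.LIGHT_ON, Location.CENTER),
            Event(3000, EventCode.LIGHT_OFF, Location.CENTER),
        ]
        with pytest.raises(ValidationError, match="no TRIAL_END"):
            build_trials(ev, probe_enabled=True)

    def test_unpaired_nose_out(self):
        ev = [
            Event(0, EventCode.TRIAL_INIT, Location.CENTER),
            Event(0, EventCode.LIGHT_ON, Location.CENTER),
            Event(3000, EventCode.LIGHT_OFF, Location.CENTER),
            Event(3500, EventCode.NOSE_OUT, Location.LEFT),
            Event(30_000, EventCode.TRIAL_END, Location.NONE),
        ]
        with pytest.raises(ValidationError, match="without a matching NOSE_IN"):
            build_trials(ev, probe_enabled=True)

    def test_bad_signal_duration(self):
        ev = [
            Event(0, EventCode.TRIAL_INIT, Location.CENTER),
            Event(0, EventCode.LIGHT_ON, Location.CENTER),
            Event(5000, EventCode.LIGHT_OFF, Location.CENTER),  # neither 3 nor 9 s
            Event(30_000, EventCode.TRIAL_END, Location.NONE),
        ]
        with pytest.raises(ValidationError, match="signal duration"):
            build_trials(ev, probe_enabled=True)


class TestSimulatedInvariants:
    def test_partition_invariant(self, sim_week2, sim_week1):
        for tl in (sim_week2[0], sim_week1):
            n = len(tl.trials)
            n_correct = sum(t.is_correct for t in tl.trials)
            n_te = sum(t.outcome is Outcome.TIME_OUT for t in tl.trials)
            n_to = sum(t.outcome is Outcome.TIMING_ERROR for t in tl.trials)
            assert n_correct + n_te + n_to == n
            assert n > 50  # a multi-day session produces a real trial count

    def test_week1_has_no_probes(self, sim_week1):
        assert all(not t.is_probe for t in sim_week1.trials)


class TestFrame:
    def test_columns_and_ranges(self, sim_week2):
        tl, _ = sim_week2
        df = trials_to_frame(tl)
        assert list(df["index"]) == list(range(len(df)))
        assert set(df["outcome"]).issubset(
            {"CORRECT_REWARDED", "CORRECT_PROBE", "TIMING_ERROR", "TIME_OUT"}
        )
        assert df["hour"].between(0, 24).all()
        assert df["hours_to_light_off"].between(-12, 12).all()
        assert df["day"].between(0, 2).all()  # 3-day session starting at light onset
        assert (df["correct"] == df["outcome"].isin(
            ["CORRECT_REWARDED", "CORRECT_PROBE"])).all()

    def test_clock_bookkeeping(self):
        tl = SubjectTimeline(
            subject_id="x", group="WT", week=1, events=[], trials=[],
            session_start_clock=datetime(2022, 3, 1, 7, 0, 0),
        )
        # session starts at light onset (07:00)
        assert tl.clock_hours(0) == pytest.approx(7.0)
        assert tl.hours_since_light_on(0) == pytest.approx(0.0)
        assert tl.circadian_day(0) == 0
        assert tl.circadian_day(24 * 3_600_000) == 1
        # light-off is 12 h after light-on
        assert tl.hours_to_light_off(0) == pytest.approx(-12.0)
        assert tl.hours_to_light_off(12 * 3_600_000) == pytest.approx(0.0)
        assert tl.hours_to_light_off(13 * 3_600_000) == pytest.approx(1.0)
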