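"""Learning-point detection: robust fit oracle, detectors, improvement."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from switchtask.learning import (
    cumulative_record,
    detect_learning_piecewise,
    detect_learning_threshold,
    huber_line,
    improvement_slopes,
    _piecewise_candidates,
    _piecewise_min_side,
    PIECEWISE_WINDOW,
)


def brute_force_piecewise(record):
    """Independent all-candidate scan with the same first-argmax rule."""
    y = np.asarray(record, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)
    diffs = []
    for c in _piecewise_candidates(n):
        lo, hi = max(0, c - PIECEWISE_WINDOW), min(n, c + PIECEWISE_WINDOW)
        sb, _ = huber_line(x[lo:c], y[lo:c])
        sa, _ = huber_line(x[c:hi], y[c:hi])
        diffs.append((c, sa - sb))
    best_c, best_d = diffs[0]
    for c, d in diffs[1:]:
        if d > best_d + 1e-12:
            best_c, best_d = c, d
    return (best_c if best_d > 0 else None), best_d


class TestHuberLine:
    def test_matches_statsmodels_rlm(self):
        """Dual route: in-package IRLS equals statsmodels RLM(HuberT)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(20, 101))
            x = np.arange(n, dtype=float)
            y = 0.5 * x + rng.normal(0, 1, n)
            out = rng.random(n) < 0.1
            y[out] += rng.normal(0, 10, n)[out]
            slope, intercept = huber_line(x, y)
            res = sm.RLM(y, sm.add_constant(x),
                         M=sm.robust.norms.HuberT(t=1.345)).fit()
            assert slope == pytest.approx(res.params[1], abs=1e-6)
            assert intercept == pytest.approx(res.params[0], abs=1e-6)

    def test_outlier_resistance(self):
        x = np.arange(50, dtype=float)
        y = 2.0 * x + 1.0
        y[10] += 100.0  # one gross outlier
        slope, intercept = huber_line(x, y)
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_exact_line_returned(self):
        x = np.arange(30, dtype=float)
        slope, intercept = huber_line(x, 3.0 * x - 2.0)
        assert slope == pytest.approx(3.0, abs=1e-9)
        assert intercept == pytest.approx(-2.0, abs=1e-9)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            huber_line([1.0], [2.0])


class TestPiecewise:
    def test_deterministic_step(self):
        """100 errors then 100 correct: V-shaped record, inflexion at 100."""
        correct = np.concatenate([np.zeros(100, bool), np.ones(100, bool)])
        res = detect_learning_piecewise(cumulative_record(correct))
        assert res.detected
        assert res.learning_trial == 100
        # slope steps from -1 to +1
        assert res.learning_rate == pytest.approx(2.0, abs=0.05)
        assert res.slope_before == pytest.approx(-1.0, abs=0.05)
        assert res.slope_after == pytest.approx(1.0, abs=0.05)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            correct = np.concatenate(
                [rng.random(300) < 0.5, rng.random(300) < 0.9]
            )
            rec = cumulative_record(correct)
            res = detect_learning_piecewise(rec)
            oracle_c, oracle_d = brute_force_piecewise(rec)
            assert res.learning_trial == oracle_c
            assert res.learning_rate == pytest.approx(oracle_d, abs=1e-12)

    def test_all_correct_has_near_zero_rate(self):
        res = detect_learning_piecewise(cumulative_record(np.ones(100, bool)))
        assert abs(res.learning_rate) < 1e-6

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_learning_piecewise(np.arange(10))

    def test_candidate_spacing(self):
        cands = _piecewise_candidates(200)
        assert all(c % 5 == 0 for c in cands)
        m = _piecewise_min_side(200)
        assert cands[0] >= m and cands[-1] <= 200 - m

    def test_locates_day_and_clock(self):
        correct = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        trials = pd.DataFrame({
            "day": np.repeat([0, 1], 50),
            "hour": np.linspace(0, 20, 100),
        })
        res = detect_learning_piecewise(cumulative_record(correct), trials)
        assert res.learning_day == 1
        assert res.learning_clock_time == pytest.approx(trials["hour"].iloc[res.learning_trial])


class TestThreshold:
    def test_exact_window(self):
        # alternating start never reaches 16/20; then all correct
        correct = np.array([i % 2 == 0 for i in range(50)] + [True] * 40)
        res = detect_learning_threshold(correct)
        assert res.detected
        t = res.learning_trial
        assert np.asarray(correct[t:t + 20]).mean() >= 0.8
        # the window ending just before it must fail the criterion
        assert np.asarray(correct[t - 1:t + 19]).mean() < 0.8

    def test_boundary_16_of_20(self):
        correct = np.array([True] * 16 + [False] * 4 + [False] * 10)
        res = detect_learning_threshold(correct)
        assert res.detected and res.learning_trial == 0

    def test_15_of_20_insufficient(self):
        correct = np.array([True] * 15 + [False] * 5)
        res = detect_learning_threshold(correct)
        assert not res.detected and res.learning_trial is None

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            detect_learning_threshold(np.ones(10, bool))


class TestImprovement:
    def test_unit_slope_when_always_correct(self):
        rows = []
        for h in range(-3, 6):  # hours around light-off, all correct
            for k in range(3):
                rows.append(dict(subject_id="s1", day=0, week=1,
                                 outcome="CORRECT_REWARDED",
                                 hours_to_light_off=h + 0.2 + 0.1 * k))
        df = pd.DataFrame(rows)
        out = improvement_slopes(df, week=1)
        assert out["slopes"]["slope"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        hourly = out["hourly"]
        assert (hourly["correct_rate"] == 1.0).all()

    def test_half_correct_gives_half_slope(self):
        rows = []
        for h in range(0, 6):
            rows.append(dict(subject_id="s1", day=0, week=1,
                             outcome="CORRECT_REWARDED",
                             hours_to_light_off=h + 0.2))
            rows.append(dict(subject_id="s1", day=0, week=1,
                             outcome="TIME_OUT",
                             hours_to_light_off=h + 0.4))
        out = improvement_slopes(pd.DataFrame(rows), week=1)
        assert out["slopes"]["slope"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_missing_post_hours_give_nan(self):
        df = pd.DataFrame([dict(subject_id="s1", day=0, week=1,
                                outcome="CORRECT_REWARDED",
                                hours_to_light_off=-2.0)])
        out = improvement_slopes(df, week=1)
        assert np.isnan(out["slopes"]["slope"].iloc[0])
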