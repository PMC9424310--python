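"""Learning-point detection and rate-of-improvement analysis.

The learning trial is read off the cumulative record of the session: a
running sum that steps +1 on each correct trial and -1 on each error
(timing error or time-out).  Two detectors are provided:

* **piecewise** — at candidate trials every 5 trials (starting at trial
  5), a robust (Huber) regression line is fitted to the 20 cumulative-
  record points before the candidate and another to the 20 after; the
  learning trial is the first candidate attaining the maximum increase in
  slope, and the learning rate is that slope difference (trials^-1);
* **threshold** — the earliest trial followed by at least 80 % correct
  over the next 20 consecutive trials.

The rate of improvement around the light-dark transition is quantified
per subject and day from hourly correct rates in a 22-hour window (10 h
before to 12 h after light-off): the cumulative correct-rate curve is
accumulated over the window's active hours and an ordinary least-squares
slope is fitted to its post-light-off part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LearningResult",
    "cumulative_record",
    "huber_line",
    "detect_learning_piecewise",
    "detect_learning_threshold",
    "improvement_slopes",
]

HUBER_T = 1.345
PIECEWISE_MIN_START = 5
PIECEWISE_STEP = 5
PIECEWISE_WINDOW = 100
PIECEWISE_MIN_SIDE = 5
THRESHOLD_WINDOW = 20
THRESHOLD_CORRECT = 0.8


@dataclass
class LearningResult:
    method: str  # "PIECEWISE" | "THRESHOLD80"
    detected: bool
    learning_trial: int | None
    learning_rate: float  # slope difference (trials^-1); NaN for THRESHOLD80
    learning_day: int | None = None
    learning_clock_time: float | None = None  # hours since light onset
    slope_before: float = float("nan")
    slope_after: float = float("nan")


def cumulative_record(correct) -> np.ndarray:
    """Cumulative sum of correct (+1) and error (-1) trials."""
    c = np.asarray(correct, dtype=bool)
    return np.cumsum(np.where(c, 1, -1))


def huber_line(x, y, t: float = HUBER_T, tol: float = 1e-10, max_iter: int = 200):
    """Robust straight-line fit by Huber IRLS with MAD scale.

    Starts from ordinary least squares; each iteration re-estimates the
    residual scale as median(|r|)/0.6745 (MAD about zero, the natural
    centring for regression residuals) and reweights points with the
    Huber weight min(1, t / |r/scale|).  Returns (slope, intercept).  A
    window whose residuals collapse to (near-)zero scale is already
    essentially a line and the current fit is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two points for a line fit")
    X = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        r = y - X @ beta
        scale = np.median(np.abs(r)) / 0.6744897501960817
        if scale < 1e-10 * max(1.0, float(np.abs(y).max())):
            break
        a = np.abs(r) / scale
        w = np.where(a <= t, 1.0, t / np.maximum(a, 1e-300))
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return float(beta[0]), float(beta[1])


def _piecewise_min_side(n: int) -> int:
    """Minimum points required on each side of a candidate.

    Slopes from very short truncated windows are so variable that a lucky
    run at the record boundary can outscore the true inflexion; demanding
    20 points per side (relaxed proportionally for short records, never
    below 5) removes those spurious boundary detections.
    """
    return max(PIECEWISE_MIN_SIDE, min(20, n // 5))


def _piecewise_candidates(n: int) -> list[int]:
    m = _piecewise_min_side(n)
    start = PIECEWISE_MIN_START
    while start < m:
        start += PIECEWISE_STEP
    return list(range(start, n - m + 1, PIECEWISE_STEP))


def detect_learning_piecewise(record, trials: pd.DataFrame | None = None) -> LearningResult:
    """Find the learning trial as the maximum-inflexion point of the
    cumulative record.

    ``record`` is the cumulative record array.  Candidates are every 5
    trials, allowing a minimum of five trials from the beginning of the
    record; at each candidate a robust line is fitted to up to 100
    cumulative-record points on either side (truncated at the record
    boundaries).  The first candidate attaining the maximum of
    (slope after - slope before) wins; the learning rate is that
    maximum.  If every slope difference is <= 0 the result is flagged as
    not detected.

    When ``trials`` (the subject's tidy trial table, in trial order) is
    given, the learning day and clock time (hours since light onset) are
    recovered from the learning trial's timestamp.
    """
    y = np.asarray(record, dtype=float)
    n = y.size
    if n < 25 or not _piecewise_candidates(n):
        raise ValueError(f"record too short for piecewise detection (got {n} trials)")
    x = np.arange(n, dtype=float)
    best_diff = -np.inf
    best = None
    for c in _piecewise_candidates(n):
        lo = max(0, c - PIECEWISE_WINDOW)
        hi = min(n, c + PIECEWISE_WINDOW)
        s_before, _ = huber_line(x[lo:c], y[lo:c])
        s_after, _ = huber_line(x[c:hi], y[c:hi])
        diff = s_after - s_before
        if diff > best_diff + 1e-12:
            best_diff = diff
            best = (c, s_before, s_after)
    c, s_b, s_a = best
    res = LearningResult(
        method="PIECEWISE",
        detected=best_diff > 0,
        learning_trial=int(c) if best_diff > 0 else None,
        learning_rate=float(best_diff),
        slope_before=s_b,
        slope_after=s_a,
    )
    if res.detected and trials is not None:
        _locate(res, trials)
    return res


def detect_learning_threshold(correct, trials: pd.DataFrame | None = None) -> LearningResult:
    """Find the earliest trial followed by >= 80 % correct over the next
    20 consecutive trials.

    ``correct`` is the per-trial boolean correctness sequence.  The
    returned learning trial is the number of trials preceding the
    qualifying run (0 if the session starts with one).
    """
    c = np.asarray(correct, dtype=bool)
    n = c.size
    if n < THRESHOLD_WINDOW:
        raise ValueError(f"need at least {THRESHOLD_WINDOW} trials")
    need = int(np.ceil(THRESHOLD_CORRECT * THRESHOLD_WINDOW))
    window_sums = np.convolve(c.astype(int), np.ones(THRESHOLD_WINDOW, dtype=int), "valid")
    hits = np.nonzero(window_sums >= need)[0]
    if hits.size == 0:
        return LearningResult(
            method="THRESHOLD80", detected=False, learning_trial=None, learning_rate=float("nan")
        )
    res = LearningResult(
        method="THRESHOLD80",
        detected=True,
        learning_trial=int(hits[0]),
        learning_rate=float("nan"),
    )
    if trials is not None:
        _locate(res, trials)
    return res


def _locate(res: LearningResult, trials: pd.DataFrame) -> None:
    row = trials.iloc[res.learning_trial]
    res.learning_day = int(row["day"])
    res.learning_clock_time = float(row["hour"])


# ---------------------------------------------------------------------------
# Rate of improvement around light-off
# ---------------------------------------------------------------------------

IMPROVEMENT_PRE_H = 10
IMPROVEMENT_POST_H = 12


def improvement_slopes(trials: pd.DataFrame, week: int | None = None) -> dict:
    """Hourly correct-rate curves around light-off and their post-light-off
    slopes.

    For each subject and day the correct rate is computed for every
    active hour in the window from 10 h before to 12 h after light-off
    (hour 0 = light-off) and accumulated into a cumulative correct-rate
    curve; when every trial is correct this curve lies on the unit-slope
    diagonal.  The slope of an OLS line through the curve's points at
    hours >= 0 is the day's rate of improvement (missing when fewer than
    two post-light-off hours have trials).

    Returns ``{"hourly": DataFrame, "slopes": DataFrame}``.
    """
    from .performance import correct_mask

    t = trials.copy()
    t["correct_w"] = correct_mask(t, week)
    t["rel_h"] = np.floor(t["hours_to_light_off"]).astype(int)
    t = t[(t["rel_h"] >= -IMPROVEMENT_PRE_H) & (t["rel_h"] < IMPROVEMENT_POST_H)]

    hourly_rows = []
    slope_rows = []
    for (subj, day), sub in t.groupby(["subject_id", "day"]):
        rates = sub.groupby("rel_h")["correct_w"].mean()
        rel = rates.index.to_numpy()
        cum = np.cumsum(rates.to_numpy(dtype=float))
        for h, r, cval in zip(rel, rates.to_numpy(), cum):
            hourly_rows.append(
                {"subject_id": subj, "day": day, "rel_h": int(h),
                 "correct_rate": float(r), "cumulative": float(cval)}
            )
        post = rel >= 0
        if post.sum() >= 2:
            slope = np.polyfit(rel[post].astype(float), cum[post], 1)[0]
        else:
            slope = float("nan")
        slope_rows.append({"subject_id": subj, "day": day, "slope": float(slope)})
    return {
        "hourly": pd.DataFrame(hourly_rows,
                               columns=["subject_id", "day", "rel_h", "correct_rate", "cumulative"]),
        "slopes": pd.DataFrame(slope_rows, columns=["subject_id", "day", "slope"]),
    }
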