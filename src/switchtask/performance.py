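"""Descriptive performance measures of the switch task.

All functions operate on the tidy per-trial DataFrame produced by
:func:`switchtask.events.trials_to_frame` (one row per classified trial,
optionally concatenated over subjects).  Performance is the ratio of
correct trials over all trials per day, where a correct trial is a
rewarded one in week 1 and a rewarded or correct-probe one in week 2.
Circadian profiles are computed hourly first and then averaged across
consecutive 3-hour intervals aligned to light onset, matching the study's
binning; "absolute number" metrics are per-day counts at each clock hour.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "correct_mask",
    "performance",
    "error_rates",
    "daily_table",
    "circadian_bin_metric",
    "reaction_times",
]

RT_GRID_MAX_S = 30.0
RT_BIN_S = 0.25


def correct_mask(trials: pd.DataFrame, week: int | None = None) -> pd.Series:
    """Boolean mask of correct trials under the week-appropriate definition.

    Week 1 has no probe trials, so correct means rewarded; in week 2
    correct probe trials count as correct as well.
    """
    if week is None:
        weeks = trials["week"].unique()
        if len(weeks) != 1:
            raise ValueError("mixed weeks in table; pass week explicitly")
        week = int(weeks[0])
    if week == 1:
        return trials["outcome"] == "CORRECT_REWARDED"
    return trials["outcome"].isin(["CORRECT_REWARDED", "CORRECT_PROBE"])


def performance(trials: pd.DataFrame, week: int | None = None) -> pd.DataFrame:
    """Per-subject, per-day performance (correct / total).

    Days with zero trials simply do not appear (missing, never 0).
    """
    t = trials.copy()
    t["correct_w"] = correct_mask(t, week)
    out = (
        t.groupby(["subject_id", "day"])
        .agg(n_trials=("correct_w", "size"), n_correct=("correct_w", "sum"))
        .reset_index()
    )
    out["performance"] = out["n_correct"] / out["n_trials"]
    return out


def error_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-day time-out and timing-error rates."""
    t = trials.copy()
    t["is_timeout"] = t["outcome"] == "TIME_OUT"
    t["is_timing_error"] = t["outcome"] == "TIMING_ERROR"
    out = (
        t.groupby(["subject_id", "day"])
        .agg(
            n_trials=("outcome", "size"),
            n_timeout=("is_timeout", "sum"),
            n_timing_error=("is_timing_error", "sum"),
        )
        .reset_index()
    )
    out["timeout_rate"] = out["n_timeout"] / out["n_trials"]
    out["timing_error_rate"] = out["n_timing_error"] / out["n_trials"]
    return out


def daily_table(trials: pd.DataFrame, week: int | None = None) -> pd.DataFrame:
    """Full per-(subject, day) metric table.

    Columns: trial/outcome counts, performance, error rates, reward rate
    (rewarded / total) and mean observed ITI.  The ITI following a trial
    is assigned to that trial's day.
    """
    t = trials.copy()
    t["correct_w"] = correct_mask(t, week)
    g = t.groupby(["subject_id", "group", "week", "day"])
    out = g.agg(
        n_trials=("outcome", "size"),
        n_rewarded=("outcome", lambda s: int((s == "CORRECT_REWARDED").sum())),
        n_probe_correct=("outcome", lambda s: int((s == "CORRECT_PROBE").sum())),
        n_timing_error=("outcome", lambda s: int((s == "TIMING_ERROR").sum())),
        n_timeout=("outcome", lambda s: int((s == "TIME_OUT").sum())),
        n_correct=("correct_w", "sum"),
        mean_iti_s=("iti_s", "mean"),
    ).reset_index()
    out["performance"] = out["n_correct"] / out["n_trials"]
    out["timeout_rate"] = out["n_timeout"] / out["n_trials"]
    out["timing_error_rate"] = out["n_timing_error"] / out["n_trials"]
    out["reward_rate"] = out["n_rewarded"] / out["n_trials"]
    return out


# ---------------------------------------------------------------------------
# Circadian (3-hour) binning
# ---------------------------------------------------------------------------

_HOURLY_METRICS: dict[str, Callable[[pd.DataFrame, int], float]] = {
    "performance": lambda d, nd: float(d["correct_w"].mean()),
    "timeout_rate": lambda d, nd: float((d["outcome"] == "TIME_OUT").mean()),
    "timing_error_rate": lambda d, nd: float((d["outcome"] == "TIMING_ERROR").mean()),
    "n_trials": lambda d, nd: len(d) / nd,
    "n_timeout": lambda d, nd: float((d["outcome"] == "TIME_OUT").sum()) / nd,
    "n_timing_error": lambda d, nd: float((d["outcome"] == "TIMING_ERROR").sum()) / nd,
    "n_rewarded": lambda d, nd: float((d["outcome"] == "CORRECT_REWARDED").sum()) / nd,
    "mean_iti_s": lambda d, nd: float(d["iti_s"].mean()),
}


def circadian_bin_metric(
    trials: pd.DataFrame,
    metric: str | Callable[[pd.DataFrame], float] = "performance",
    bin_h: int = 3,
    week: int | None = None,
) -> pd.DataFrame:
    """Per-subject circadian profile of a metric in ``bin_h``-hour bins.

    The metric is evaluated for each clock hour (hours since light onset,
    pooling days; count metrics are normalised per day) and the hourly
    values are then averaged within consecutive ``bin_h``-hour intervals.
    Hours with zero trials are excluded from their bin's average, and a
    bin whose hours are all empty is missing from the output.
    """
    if 24 % bin_h != 0:
        raise ValueError("bin_h must divide 24")
    t = trials.copy()
    t["correct_w"] = correct_mask(t, week)
    t["hour_i"] = np.floor(t["hour"]).astype(int) % 24
    if callable(metric):
        f = lambda d, nd: float(metric(d))  # noqa: E731
        name = getattr(metric, "__name__", "metric")
    else:
        try:
            f = _HOURLY_METRICS[metric]
        except KeyError:
            raise ValueError(f"unknown metric {metric!r}") from None
        name = metric

    rows = []
    for subj, sub in t.groupby("subject_id"):
        n_days = max(int(sub["day"].nunique()), 1)
        hourly = {
            h: f(d, n_days) for h, d in sub.groupby("hour_i")
        }
        for b0 in range(0, 24, bin_h):
            vals = [hourly[h] for h in range(b0, b0 + bin_h) if h in hourly]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                rows.append(
                    {"subject_id": subj, "bin_start_h": b0, name: float(np.mean(vals))}
                )
    return pd.DataFrame(rows, columns=["subject_id", "bin_start_h", name])


# ---------------------------------------------------------------------------
# Reaction times
# ---------------------------------------------------------------------------


def reaction_times(trials: pd.DataFrame) -> dict:
    """Per-subject empirical reaction-time PDFs and their group summary.

    The reaction time of a responding (non-time-out) trial is the delay
    from signal end to the first poke at the type-associated hopper.  PDFs
    are histograms on a fixed 0-30 s grid with 0.25 s bins, normalised to
    integrate to 1 over responders.  Returns bin centres, a per-subject
    PDF DataFrame and the across-subject mean +/- SEM (n = subjects).
    """
    edges = np.arange(0.0, RT_GRID_MAX_S + RT_BIN_S / 2, RT_BIN_S)
    centers = edges[:-1] + RT_BIN_S / 2
    resp = trials[(trials["outcome"] != "TIME_OUT") & trials["reaction_time_s"].notna()]
    pdfs = {}
    for subj, sub in resp.groupby("subject_id"):
        rt = sub["reaction_time_s"].to_numpy(dtype=float)
        rt = rt[np.isfinite(rt)]
        if rt.size == 0:
            continue
        hist, _ = np.histogram(np.clip(rt, 0, RT_GRID_MAX_S - 1e-9), bins=edges)
        pdfs[subj] = hist / (hist.sum() * RT_BIN_S)
    pdf_df = pd.DataFrame(pdfs, index=centers)
    if pdf_df.shape[1]:
        mean = pdf_df.mean(axis=1)
        sem = pdf_df.std(axis=1, ddof=1) / np.sqrt(pdf_df.shape[1]) if pdf_df.shape[1] > 1 else mean * np.nan
    else:
        mean = pd.Series(dtype=float)
        sem = pd.Series(dtype=float)
    return {"centers_s": centers, "pdf_per_subject": pdf_df, "mean": mean, "sem": sem}
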