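"""End-to-end pipeline orchestration.

A single YAML configuration drives simulate -> validate/trials ->
metrics -> learning -> timing -> circadian -> stats, with every stage
writing plain CSV intermediates (consumable from R or Matlab) and a JSON
manifest recording the seed, the configuration hash and the produced
files.  Runs are deterministic for a fixed seed.

Configuration schema (all sections optional except one of
``simulate``/``logs``)::

    seed: 1
    outdir: out
    simulate:
      session_days: 3
      week: 2
      task: {}                      # TaskConfig overrides
      groups:
        WT: {n_subjects: 2, mouse: {mu_s: 6.0, cv: 0.15}}
        KO: {n_subjects: 2, mouse: {p_err_post: 0.05}}
    logs: [path1.csv, path2.csv]    # alternative to simulate
    stages: {metrics: true, learning: true, timing: true,
             circadian: true, stats: true}
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import circadian as circ
from . import learning as learn
from . import timing
from .performance import (
    circadian_bin_metric,
    daily_table,
    performance as daily_performance,
    reaction_times,
)
from .events import SubjectTimeline, read_event_log, trials_to_frame, write_event_log
from .simulate import MouseConfig, TaskConfig, simulate_subject
from .stats import two_way_repeated_anova

__all__ = ["run_pipeline", "load_config", "simulate_cohort"]

log = logging.getLogger("switchtask")

DEFAULT_STAGES = {"metrics": True, "learning": True, "timing": True, "circadian": True, "stats": True}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("pipeline config must set an explicit seed")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _subject_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 100_003 + 7919 * index + 1) % 2**31)


def simulate_cohort(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    """Simulate every configured subject and write one event log each."""
    sim = cfg["simulate"]
    week = int(sim.get("week", 1))
    task_kwargs = dict(sim.get("task", {}))
    task_kwargs.setdefault("session_days", int(sim.get("session_days", 7)))
    task = TaskConfig.for_week(week, **task_kwargs)
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    paths = []
    idx = 0
    for group, gcfg in sim["groups"].items():
        n = int(gcfg.get("n_subjects", 1))
        mouse_kwargs = dict(gcfg.get("mouse", {}))
        for k in range(n):
            subject_id = f"{group.lower()}{k + 1}"
            mouse = MouseConfig(seed=_subject_seed(seed, idx), **mouse_kwargs)
            tl = simulate_subject(task, mouse, subject_id=subject_id, group=group, week=week)
            p = logdir / f"{subject_id}.csv"
            write_event_log(tl, p)
            log.info("simulated %s (%s): %d trials", subject_id, group, len(tl.trials))
            paths.append(p)
            idx += 1
    return paths


def _stage_learning(timelines: list[SubjectTimeline], trials: pd.DataFrame, outdir: Path) -> list[Path]:
    rows = []
    for tl in timelines:
        sub = trials[trials["subject_id"] == tl.subject_id].sort_values("index")
        rec = learn.cumulative_record(sub["correct"].to_numpy())
        for method, res in (
            ("piecewise", _safe(lambda: learn.detect_learning_piecewise(rec, sub))),
            ("threshold", _safe(lambda: learn.detect_learning_threshold(sub["correct"].to_numpy(), sub))),
        ):
            if res is None:
                continue
            rows.append(
                dict(subject_id=tl.subject_id, group=tl.group, method=res.method,
                     detected=res.detected, learning_trial=res.learning_trial,
                     learning_rate=res.learning_rate, learning_day=res.learning_day,
                     learning_clock_time=res.learning_clock_time)
            )
    out = [outdir / "learning.csv"]
    pd.DataFrame(rows).to_csv(out[0], index=False)
    imp = learn.improvement_slopes(trials)
    imp["slopes"].to_csv(outdir / "improvement_slopes.csv", index=False)
    imp["hourly"].to_csv(outdir / "improvement_hourly.csv", index=False)
    out += [outdir / "improvement_slopes.csv", outdir / "improvement_hourly.csv"]
    return out


def _stage_timing(timelines: list[SubjectTimeline], outdir: Path) -> list[Path]:
    rows = []
    for tl in timelines:
        lat = timing.extract_switch_latencies(tl.trials)
        try:
            fit = timing.fit_switch_gaussian(lat)
        except (timing.InsufficientDataError, timing.DegenerateFitError) as exc:
            log.warning("timing fit skipped for %s: %s", tl.subject_id, exc)
            continue
        rows.append(
            dict(subject_id=tl.subject_id, group=tl.group, mu_s=fit.mu_s,
                 sigma_s=fit.sigma_s, cv=fit.cv, n_switches=fit.n_switches,
                 expected_gain=timing.expected_gain(fit.mu_s, fit.cv))
        )
    files = [outdir / "switch_fits.csv"]
    pd.DataFrame(rows).to_csv(files[0], index=False)
    surf = timing.eg_surface()
    pd.DataFrame({"cv": surf.cv_grid, "optimal_mu_s": surf.optimum_curve}).to_csv(
        outdir / "eg_optimum_curve.csv", index=False
    )
    files.append(outdir / "eg_optimum_curve.csv")
    return files


def _stage_circadian(timelines: list[SubjectTimeline], outdir: Path) -> list[Path]:
    rows = []
    for tl in timelines:
        try:
            fit = circ.fit_circadian(circ.bin_pokes(tl))
        except (ValueError, circ.CircadianFitError) as exc:
            log.warning("circadian fit skipped for %s: %s", tl.subject_id, exc)
            continue
        rows.append(
            dict(subject_id=tl.subject_id, group=tl.group, A=fit.amplitude_A,
                 P_h=fit.period_P_h, phi=fit.phase_phi, cc=fit.cc)
        )
    p = outdir / "circadian.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return [p]


def _stage_stats(trials: pd.DataFrame, outdir: Path) -> list[Path]:
    rows = []
    daily = daily_performance(trials)
    groups = trials.drop_duplicates("subject_id").set_index("subject_id")["group"]
    daily["group"] = daily["subject_id"].map(groups)
    # keep only days every subject has (balanced repeated-measures grid)
    n_subj = daily["subject_id"].nunique()
    full_days = daily.groupby("day")["subject_id"].nunique()
    keep = full_days[full_days == n_subj].index
    d = daily[daily["day"].isin(keep)].rename(columns={"day": "time", "performance": "value"})
    try:
        an = two_way_repeated_anova(d)
        for _, r in an.iterrows():
            rows.append(dict(analysis="performance_by_day", factor=r["factor"],
                             statistic=r["F"], p=r["p"], df1=r["df1"], df2=r["df2"]))
    except ValueError as exc:
        log.warning("ANOVA skipped: %s", exc)
    p = outdir / "stats.csv"
    pd.DataFrame(rows, columns=["analysis", "factor", "statistic", "p", "df1", "df2"]).to_csv(
        p, index=False
    )
    return [p]


def _safe(fn):
    try:
        return fn()
    except ValueError as exc:
        log.warning("learning detection skipped: %s", exc)
        return None


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured pipeline end to end; returns the manifest dict.

    The manifest (also written to ``<outdir>/manifest.json``) records the
    package version, the seed, the configuration hash and the files each
    stage produced.  A stage failure aborts the run with an error naming
    the stage.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    if "seed" not in cfg:
        raise ValueError("pipeline config must set an explicit seed")
    seed = int(cfg["seed"])
    outdir = Path(cfg.get("outdir", "switchtask_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {**DEFAULT_STAGES, **cfg.get("stages", {})}
    manifest: dict = {
        "package": "switchtask",
        "version": _pkg_version("switchtask"),
        "seed": seed,
        "config_sha256": _config_hash(cfg),
        "stages": {},
    }

    def run_stage(name, fn):
        try:
            files = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = [str(f) for f in files]
        log.info("stage %s -> %d file(s)", name, len(files))

    if "simulate" in cfg:
        run_stage("simulate", lambda: simulate_cohort(cfg, outdir, seed))
        log_paths = manifest["stages"]["simulate"]
    elif "logs" in cfg:
        log_paths = [str(p) for p in cfg["logs"]]
    else:
        raise ValueError("config needs a 'simulate' section or a 'logs' list")

    timelines = [read_event_log(p) for p in log_paths]
    trials = pd.concat([trials_to_frame(tl) for tl in timelines], ignore_index=True)

    def stage_trials():
        p = outdir / "trials.csv"
        trials.to_csv(p, index=False)
        return [p]

    run_stage("trials", stage_trials)

    if stages.get("metrics"):
        def stage_metrics():
            files = []
            daily_table(trials).to_csv(outdir / "metrics_daily.csv", index=False)
            files.append(outdir / "metrics_daily.csv")
            parts = [
                circadian_bin_metric(trials, m).set_index(["subject_id", "bin_start_h"])
                for m in ("performance", "n_trials", "timeout_rate", "timing_error_rate")
            ]
            pd.concat(parts, axis=1).reset_index().to_csv(
                outdir / "metrics_circadian.csv", index=False
            )
            files.append(outdir / "metrics_circadian.csv")
            rt = reaction_times(trials)
            rt["pdf_per_subject"].rename_axis("rt_s").to_csv(outdir / "reaction_time_pdf.csv")
            files.append(outdir / "reaction_time_pdf.csv")
            return files

        run_stage("metrics", stage_metrics)
    if stages.get("learning"):
        run_stage("learning", lambda: _stage_learning(timelines, trials, outdir))
    if stages.get("timing"):
        run_stage("timing", lambda: _stage_timing(timelines, outdir))
    if stages.get("circadian"):
        run_stage("circadian", lambda: _stage_circadian(timelines, outdir))
    if stages.get("stats"):
        run_stage("stats", lambda: _stage_stats(trials, outdir))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
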