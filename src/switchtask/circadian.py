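"""Circadian rhythm estimation from nose-poke activity.

The subjective circadian period is estimated by fitting the sinusoid

    F(t) = A * sin(2*pi/P * t + phi) + A

to the binned nose-poke counts (15-minute bins by default), where ``A`` is
the amplitude (which also sets the offset so that F >= 0), ``P`` the
period in hours and ``phi`` the phase.  The nonlinear least-squares fit is
restarted from every period initialisation on a 21-27 h grid in 0.5 h
steps and the converged fit with the lowest mean-square error is
returned.  Goodness of fit is the Pearson correlation between the data
and the fitted curve (undefined, reported as NaN, for zero-variance
data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .events import EventCode, SubjectTimeline

__all__ = ["CircadianFit", "CircadianFitError", "bin_pokes", "fit_circadian", "sinusoid"]

#: Initialisation grid for the period (hours).
PERIOD_GRID_H = np.arange(21.0, 27.0 + 1e-9, 0.5)
PERIOD_BOUNDS_H = (21.0, 27.0)
#: Minimum data span: two full cycles of the shortest admissible period.
MIN_SPAN_H = 2.0 * PERIOD_BOUNDS_H[0]


class CircadianFitError(RuntimeError):
    """All restarts of the sinusoidal fit failed; carries per-restart status."""

    def __init__(self, statuses):
        self.statuses = statuses
        super().__init__(f"circadian fit failed for every initialisation: {statuses}")


@dataclass(frozen=True)
class CircadianFit:
    amplitude_A: float
    period_P_h: float
    phase_phi: float
    cc: float  # NaN when undefined (zero-variance data)
    bin_minutes: float
    mse: float
    n_bins: int


def sinusoid(t_h: np.ndarray, A: float, P: float, phi: float) -> np.ndarray:
    """The fitted periodic activity curve, F(t) = A sin(2*pi/P t + phi) + A."""
    return A * np.sin(2.0 * np.pi / P * np.asarray(t_h, dtype=float) + phi) + A


def bin_pokes(timeline: SubjectTimeline, bin_minutes: float = 15.0) -> pd.Series:
    """Count all NOSE_IN events in contiguous bins from session start.

    Returns a Series of counts indexed by bin start time in hours.
    """
    if not timeline.events:
        raise ValueError("cannot bin pokes of an empty timeline")
    ts = np.array(
        [e.timestamp_ms for e in timeline.events if e.code is EventCode.NOSE_IN],
        dtype=np.int64,
    )
    bin_ms = bin_minutes * 60_000.0
    last = timeline.events[-1].timestamp_ms
    n_bins = int(np.floor(last / bin_ms)) + 1
    counts = np.zeros(n_bins, dtype=int)
    if ts.size:
        idx = (ts / bin_ms).astype(int)
        np.add.at(counts, idx, 1)
    hours = np.arange(n_bins) * bin_minutes / 60.0
    return pd.Series(counts, index=hours, name="pokes")


def fit_circadian(counts, bin_minutes: float = 15.0) -> CircadianFit:
    """Fit the periodic activity model to a binned count series.

    ``counts`` may be the Series produced by :func:`bin_pokes` (its index
    supplies the bin times in hours) or a plain array, in which case bins
    of ``bin_minutes`` from time zero are assumed.  Each restart seeds the
    period from the 21-27 h grid; amplitude and phase are seeded from the
    linear (sine/cosine) regression at that period.  The reported fit is
    the converged restart with the smallest mean-square error, so the
    result does not depend on the order of the initialisation grid.
    """
    if isinstance(counts, pd.Series):
        y = counts.to_numpy(dtype=float)
        t = counts.index.to_numpy(dtype=float)
    else:
        y = np.asarray(counts, dtype=float)
        t = np.arange(y.size) * bin_minutes / 60.0
    if y.size < 4:
        raise ValueError("too few bins for a circadian fit")
    span = t[-1] - t[0]
    if span < MIN_SPAN_H:
        raise ValueError(
            f"need at least {MIN_SPAN_H:.0f} h of data (two full cycles); got {span:.1f} h"
        )

    def residuals(params):
        A, P, phi = params
        return sinusoid(t, A, P, phi) - y

    lo = np.array([0.0, PERIOD_BOUNDS_H[0], -np.pi])
    hi = np.array([np.inf, PERIOD_BOUNDS_H[1], np.pi])
    results = []
    statuses = []
    for P0 in PERIOD_GRID_H:
        A0, phi0 = _linear_seed(t, y, P0)
        x0 = np.clip([A0, P0, phi0], lo, np.minimum(hi, 1e12))
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), ftol=1e-10, xtol=1e-10)
        except Exception as exc:  # pragma: no cover - defensive
            statuses.append((float(P0), f"error: {exc}"))
            continue
        statuses.append((float(P0), f"status {sol.status}"))
        if sol.status > 0:
            mse = float(np.mean(sol.fun**2))
            results.append((mse, float(P0), sol.x))
    if not results:
        raise CircadianFitError(statuses)
    results.sort(key=lambda r: (r[0], r[1]))
    mse, _p0, (A, P, phi) = results[0]

    fitted = sinusoid(t, A, P, phi)
    if np.std(y) == 0.0 or np.std(fitted) == 0.0:
        cc = float("nan")
    else:
        cc = float(pearsonr(y, fitted).statistic)
    return CircadianFit(
        amplitude_A=float(A),
        period_P_h=float(P),
        phase_phi=float(phi),
        cc=cc,
        bin_minutes=float(bin_minutes),
        mse=float(mse),
        n_bins=int(y.size),
    )


def _linear_seed(t: np.ndarray, y: np.ndarray, P0: float) -> tuple[float, float]:
    """Amplitude/phase warm start at a fixed trial period.

    At fixed P the model is linear in (a, b, c) for
    a sin(wt) + b cos(wt) + c; the seed ties the offset back to the
    amplitude as the model requires.
    """
    w = 2.0 * np.pi / P0
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef
    amp = float(np.hypot(a, b))
    A0 = max(0.5 * (amp + max(c, 0.0)), 1e-9)
    phi0 = float(np.arctan2(b, a))
    return A0, phi0
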