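"""Switch-latency timing analysis and the expected-gain optimality model.

On long trials a well-trained animal first waits at the short hopper and,
once the short target time has elapsed without reward, switches to the
long hopper.  The **switch latency** is the trial time at which it leaves
the short-latency location for the long-latency one; its distribution is
summarised by a Gaussian fit whose mean mu is the timing accuracy and
whose coefficient of variation CV = sigma/mu is the endogenous timing
uncertainty.

The optimality of a timed switch policy is scored by the expected-gain
function

    EG(mu, sigma) = 1 - Phi(T_S; mu, sigma) + Phi(T_L; mu, sigma)

with Phi the normal CDF and T_S = 3 s, T_L = 9 s: the two terms are the
probabilities of still being at the short hopper when a short signal ends
and of having switched before a long signal ends, i.e. the probability of
a correct response on each trial type.  The normalised EG surface over a
(mu, CV) grid and its per-CV maximiser describe the optimal target switch
latency at each level of timing uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .events import Location, Outcome, TrialRecord, TrialType

__all__ = [
    "SwitchFit",
    "EGSurface",
    "InsufficientDataError",
    "DegenerateFitError",
    "extract_switch_latencies",
    "fit_switch_gaussian",
    "expected_gain",
    "eg_surface",
    "probe_np_distribution",
]

T_SHORT_S = 3.0
T_LONG_S = 9.0
MIN_SWITCHES_FOR_FIT = 10

#: Default expected-gain surface grids.
MU_GRID_DEFAULT = np.arange(3.0, 9.0 + 1e-9, 0.05)
CV_GRID_DEFAULT = np.arange(0.01, 0.5 + 1e-9, 0.005)


class InsufficientDataError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class SwitchFit:
    mu_s: float
    sigma_s: float
    cv: float
    n_switches: int


@dataclass(frozen=True)
class EGSurface:
    mu_grid: np.ndarray
    cv_grid: np.ndarray
    eg: np.ndarray  # shape (len(cv_grid), len(mu_grid)), max-normalised to 1
    optimum_curve: np.ndarray  # per-CV mu maximising EG


def extract_switch_latencies(trials: list[TrialRecord]) -> np.ndarray:
    """Switch latencies (seconds from signal onset) of long trials with an
    observed short-to-long hopper transition.

    The latency is the final NOSE_OUT at the short (left) hopper that
    precedes the first NOSE_IN at the long (right) hopper; long trials
    without such a transition (including those where the animal never
    left the short hopper, censored at the long target) are excluded.
    Short trials contribute nothing by definition.
    """
    lat = []
    for tr in trials:
        if tr.trial_type is not TrialType.LONG:
            continue
        first_right_in = None
        for loc, t_in, _t_out in tr.pokes:
            if loc is Location.RIGHT:
                first_right_in = t_in
                break
        if first_right_in is None:
            continue
        left_outs = [
            t_out
            for loc, _t_in, t_out in tr.pokes
            if loc is Location.LEFT and t_out <= first_right_in
        ]
        if not left_outs:
            continue
        lat.append((max(left_outs) - tr.start_ms) / 1000.0)
    return np.asarray(lat, dtype=float)


def fit_switch_gaussian(latencies) -> SwitchFit:
    """Maximum-likelihood Gaussian fit of the switch-latency distribution.

    Returns the accuracy mu (sample mean), spread sigma (sample SD) and
    uncertainty CV = sigma/mu.
    """
    x = np.asarray(latencies, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_SWITCHES_FOR_FIT:
        raise InsufficientDataError(
            f"need >= {MIN_SWITCHES_FOR_FIT} switch latencies, got {x.size}"
        )
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    if sigma == 0.0:
        raise DegenerateFitError("switch latencies have zero variance")
    return SwitchFit(mu_s=mu, sigma_s=sigma, cv=sigma / mu, n_switches=int(x.size))


def expected_gain(
    mu: float, cv: float, t_short: float = T_SHORT_S, t_long: float = T_LONG_S
) -> float:
    """Un-normalised expected gain of a Normal(mu, cv*mu) switch policy.

    ``1 - Phi(T_S; mu, sigma) + Phi(T_L; mu, sigma)`` — the sum of the
    correct-response probabilities on short and long trials.  Approaches 2
    as cv -> 0 for mu strictly inside (T_S, T_L).
    """
    if mu <= 0 or cv <= 0:
        raise ValueError("mu and cv must be positive")
    sigma = cv * mu
    return float(1.0 - norm.cdf(t_short, mu, sigma) + norm.cdf(t_long, mu, sigma))


def eg_surface(
    mu_grid=None, cv_grid=None, t_short: float = T_SHORT_S, t_long: float = T_LONG_S
) -> EGSurface:
    """Normalised expected-gain surface over a (mu, CV) grid.

    Values are divided by the grid maximum so the surface peaks at 1; the
    optimum curve holds, for each CV, the mu maximising EG (ties broken
    toward the smaller mu).
    """
    mu = MU_GRID_DEFAULT.copy() if mu_grid is None else np.asarray(mu_grid, dtype=float)
    cv = CV_GRID_DEFAULT.copy() if cv_grid is None else np.asarray(cv_grid, dtype=float)
    if mu.size == 0 or cv.size == 0:
        raise ValueError("empty grid")
    if np.any(mu <= 0) or np.any(mu > 30) or np.any(cv <= 0) or np.any(cv > 1):
        raise ValueError("grids must lie in (0, 30] (mu) and (0, 1] (cv)")
    M, C = np.meshgrid(mu, cv)  # shape (n_cv, n_mu)
    S = C * M
    eg = 1.0 - norm.cdf(t_short, M, S) + norm.cdf(t_long, M, S)
    eg_norm = eg / eg.max()
    opt_idx = np.argmax(eg, axis=1)  # argmax returns the first (smallest mu) at ties
    return EGSurface(mu_grid=mu, cv_grid=cv, eg=eg_norm, optimum_curve=mu[opt_idx])


# ---------------------------------------------------------------------------
# Probe-trial nose-poke occupancy
# ---------------------------------------------------------------------------

PROBE_BIN_S = 0.1
PROBE_WINDOW_S = 30.0


def probe_np_distribution(trials: list[TrialRecord]) -> dict:
    """Nose-poke occupancy distributions of probe trials.

    Occupancy rasters are accumulated at 0.1 s resolution over the 0-30 s
    trial window.  Short probes are characterised by their short-hopper
    occupancy, long probes by both hoppers separately; each histogram is
    normalised to sum to 1, and each comes with its (monotone, 0 -> 1)
    cumulative curve.  Raises when the input contains no correct probe
    trials (probe identity is only observable on correct responses).
    """
    edges = np.arange(0.0, PROBE_WINDOW_S + PROBE_BIN_S / 2, PROBE_BIN_S)
    centers = edges[:-1] + PROBE_BIN_S / 2
    keys = [("SHORT", Location.LEFT), ("LONG", Location.LEFT), ("LONG", Location.RIGHT)]
    occ = {k: np.zeros(centers.size) for k in keys}
    rasters: dict[tuple[str, str], list[np.ndarray]] = {k[0] + "_" + k[1].value: [] for k in keys}
    n_probe = 0
    for tr in trials:
        if tr.outcome is not Outcome.CORRECT_PROBE:
            continue
        n_probe += 1
        for ttype, loc in keys:
            if tr.trial_type.value != ttype:
                continue
            row = np.zeros(centers.size)
            for ploc, t_in, t_out in tr.pokes:
                if ploc is not loc:
                    continue
                a = (t_in - tr.start_ms) / 1000.0
                b = (t_out - tr.start_ms) / 1000.0
                row += np.clip(
                    (np.minimum(edges[1:], b) - np.maximum(edges[:-1], a)) / PROBE_BIN_S,
                    0.0,
                    1.0,
                )
            occ[(ttype, loc)] += row
            rasters[ttype + "_" + loc.value].append(row)
    if n_probe == 0:
        raise InsufficientDataError("no correct probe trials in input")

    hist = {}
    cumulative = {}
    for k in keys:
        name = k[0] + "_" + k[1].value
        total = occ[k].sum()
        h = occ[k] / total if total > 0 else occ[k]
        hist[name] = h
        cumulative[name] = np.cumsum(h)
    return {
        "centers_s": centers,
        "histogram": hist,
        "cumulative": cumulative,
        "n_probe_trials": n_probe,
        "rasters": {k: np.array(v) if v else np.zeros((0, centers.size)) for k, v in rasters.items()},
    }
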