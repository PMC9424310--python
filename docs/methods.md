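# Methods note

This note records the models implemented in `switchtask`, the default
parameter values and their units, what the synthetic-subject simulator
does and does not emulate, and the numerical choices that affect results.

## 1. Event model and trial classification

An event log is a CSV with four `#`-header lines (subject id, group,
week, session start clock time) followed by `timestamp_ms,code,location`
rows. Codes: `TRIAL_INIT`, `LIGHT_ON`/`LIGHT_OFF` (signal at the centre
hopper), `NOSE_IN`/`NOSE_OUT`, `PELLET`, `TRIAL_END`,
`HOUSE_LIGHT_ON`/`HOUSE_LIGHT_OFF`. Locations: `CENTER`, `LEFT`,
`RIGHT`, `NONE`.

Classification of a trial (signal duration from the first
`LIGHT_ON`/`LIGHT_OFF` pair; must be exactly 3000 or 9000 ms):

* the **first lateral `NOSE_IN` at or after signal end** resolves the
  trial: the type-matching hopper (short→left, long→right) gives
  `CORRECT_REWARDED` when a `PELLET` occurs in the trial, else
  `CORRECT_PROBE` (only in probe-enabled sessions); the other hopper
  gives `TIMING_ERROR`;
* no resolving poke within 30 s gives `TIME_OUT` (response time recorded
  as exactly 30 s after initiation);
* pokes before signal end never resolve a trial — they are part of the
  normal wait-and-switch strategy.

Rationale: this rule is the unique resolution semantics consistent with
the decision model of §4 — a short trial is correct iff the planned
switch time exceeds 3 s, a long trial iff it is below 9 s — and with the
observation that, on long trials, animals routinely occupy the short
hopper between 3 and 9 s without ending the trial.

Consequences worth knowing:

* **Probe identifiability.** The log marks probes only implicitly (a
  correct response without a pellet), so `is_probe` is true exactly for
  `CORRECT_PROBE` trials; probe trials that end in a timing error or
  time-out are indistinguishable from regular ones and are counted with
  them.
* **ITI validation.** The scheduled inter-trial interval is not in the
  log; the reader enforces the verifiable part, a 30 s lockout between
  `TRIAL_END` and the next `TRIAL_INIT`. The recorded `iti_s` is the
  *observed* end-to-init interval.
* Validation also rejects unpaired pokes, nested `TRIAL_INIT`s, missing
  `TRIAL_END`s, malformed signal durations and (in probe-free sessions)
  unrewarded correct responses.

## 2. Task scheduler

`TaskConfig` holds the published task constants (defaults): short signal
3 s, long 9 s, `p_short = 0.5`, probe probability 0 (week 1) or 0.2
(week 2), time-out 30 s, ITI = 30 s fixed + geometric random part. The
geometric part lives on integer seconds {0, 1, 2, …} with mean 60 s
(success parameter 1/61), the natural discrete reading of "geometric
with a mean of 60 s". Lights on 07:00–19:00; sessions default to 7 days
starting at light onset.

## 3. Synthetic mouse

`MouseConfig` defaults (ground truth for recovery tests):

| parameter | default | units | meaning |
|---|---|---|---|
| `mu_s` | 6.0 | s | mean planned switch latency (timing accuracy); mid-interval, near-optimal |
| `cv` | 0.15 | – | switch-latency CV (timing uncertainty); scalar-timing range |
| `p_timeout_light` / `p_timeout_dark` | 0.25 / 0.08 | – | per-trial lapse (disengagement) probability by phase; sleepier in the light (rest) phase |
| `init_rate_light` / `init_rate_dark` | 5 / 15 | trials/h | base trial-initiation rates; nocturnal activity |
| `circadian_amplitude`, `period_h`, `phase_rad` | 0.6, 24, −π | –, h, rad | sinusoidal modulation of the initiation rate |
| `learning_trial_true` | 150 | trials | error probability steps down here |
| `p_err_pre` / `p_err_post` | 0.5 / 0.1 | – | timing-error probability before/after learning |

Generation per trial: initiation times come from a thinned Poisson
process with rate `base(phase) × (1 + modulation)`, suspended during
trials and ITIs. Engagement is Bernoulli (1 − lapse); a lapsed trial
becomes a time-out with desultory centre pokes. An engaged trial draws
its intended correctness (error probability per the learning step) and
then a planned switch time `t_sw` from a normal N(μ, (cv·μ)²) truncated
to the region implying the intended outcome (e.g. a correct short trial
requires `t_sw > 3 s`). Long trials with `t_sw ≥ 9 s` are *censored*:
the animal never leaves the short hopper and the trial resolves as a
timing error there. Event emission places the last short-hopper
`NOSE_OUT` exactly at `t_sw` on switch trials, fills hopper occupancy
with realistic poke bouts, and emits the resolving poke shortly after
signal end (uniform 0.15–0.6 s), so the classifier's outcome equals the
intended outcome trial by trial (tested).

The simulator does **not** emulate: pre-training/shaping, satiety or
weight regulation, social behaviour, drift or ultradian structure in
timing parameters, apparatus noise (missed detections, double
triggers), or reward-magnitude effects. Its purpose is ground-truth
recoverability, not behavioural realism beyond the analysed quantities.

## 4. Switch-latency timing model and expected gain

On long trials, the switch latency is the last `NOSE_OUT` at the short
hopper preceding the first `NOSE_IN` at the long hopper, measured from
trial start. Trials without an observed short→long transition (including
censored ones) are excluded. The Gaussian fit is the sample mean μ and
SD σ (maximum-likelihood), with CV = σ/μ; at least 10 latencies are
required and zero variance is rejected.

The expected gain of a Normal(μ, σ) switch policy is
`EG = 1 − Φ(3; μ, σ) + Φ(9; μ, σ)`, i.e. P(correct | short) +
P(correct | long); its maximum over μ at fixed CV is the optimal target
switch latency. The surface is evaluated on μ ∈ [3, 9] in 0.05 s steps
and CV ∈ [0.01, 0.5] in 0.005 steps, normalised by its maximum; per-CV
argmax ties break toward the smaller μ. The closed form is verified
against Monte-Carlo simulation, and the grid optimum against a 10× finer
scan, in the acceptance tests.

Probe-trial occupancy distributions (time in each hopper across the
0–30 s window, 0.1 s bins, overlap-fraction binning) are computed from
correct probe trials only, since those are the identifiable ones.

## 5. Learning detection

The cumulative record steps +1 on correct and −1 on error trials.

* **Piecewise detector**: candidate trials every 5 trials; at each
  candidate, straight lines are fitted to up to 100 record points on
  either side by Huber-robust regression; the learning trial is the
  first candidate attaining the maximal slope difference (post − pre),
  and that difference is the learning rate (trials⁻¹). A minimum of
  `max(5, min(20, n/5))` points per side is required. The window sizes
  are a package design choice validated by change-point recovery:
  20-point side windows recover a 0.5→0.9 step at trial 300 of a
  600-trial record within ±25 trials in only ~62/100 seeded runs
  (short-window slope noise outscores the true inflexion), while
  100-point windows with the minimum-side rule recover ≥ 95/100. The
  detector equals a brute-force all-candidate scan by construction and
  is tested against one.
* **Huber line fit**: iteratively reweighted least squares, tuning
  constant 1.345, scale re-estimated each iteration as median|r|/0.6745
  (MAD about zero). This matches `statsmodels` RLM(HuberT) to ~1e-9,
  which serves as the independent oracle in the tests.
* **Threshold detector**: earliest trial followed by ≥ 16 of 20 correct
  (≥ 80 %) in the next 20 consecutive trials.
* **Improvement slopes**: per subject and day, hourly correct rates in a
  −10 h…+12 h window around light-off are accumulated into a cumulative
  correct-rate curve (unit slope when all trials are correct); the OLS
  slope of its post-light-off part is the day's rate of improvement.

## 6. Circadian period

Nose-poke counts in 15-minute bins are fitted with
`F(t) = A sin(2π/P t + φ) + A` (amplitude ties the offset so F ≥ 0) by
bounded nonlinear least squares (`A ≥ 0`, `P ∈ [21, 27] h`,
`φ ∈ [−π, π]`), restarted from every period on the 21–27 h grid in 0.5 h
steps; amplitude and phase are warm-started from the linear sine/cosine
regression at the trial period. The converged restart with the lowest
mean-square error wins, so the result is independent of grid order.
Goodness of fit is the Pearson correlation between data and fitted
curve (NaN for zero-variance data — note the model cannot represent a
nonzero constant exactly, since the offset is tied to the amplitude).
At least two full 21 h cycles (42 h) of data are required.

## 7. Group statistics

The group comparison is a mixed-design (split-plot) ANOVA: genotype
group between subjects, time (day/hour/bin) within. Sums of squares are
the classical balanced-design ones; the group effect is tested against
the subject-within-group mean square, time and interaction against the
residual (subject × time) mean square, with no sphericity correction.
The implementation requires a complete subject-by-time grid (incomplete
designs are rejected, not imputed) and matches `pingouin.mixed_anova`
(uncorrected p) exactly, which the tests verify for equal and unequal
group sizes. Distributional comparisons of per-subject parameters use
the two-sample Kolmogorov–Smirnov test (`scipy`, asymptotic p).

## 8. Pipeline and determinism

`run_pipeline` drives simulate → classify → metrics → learning → timing
→ circadian → stats from one YAML config with a mandatory seed, writing
plain CSV intermediates and a JSON manifest (package version, seed,
config SHA-256, files per stage). Subject seeds derive deterministically
from the run seed and stay below 2³¹; identical configs reproduce
outputs byte for byte. Stages can be toggled; a stage failure aborts the
run with an error naming the stage.

## 9. Limitations

* Probe trials ending in errors or time-outs cannot be identified from
  the log (see §1) — probe-specific analyses are conditioned on correct
  probes.
* The switch-latency fit ignores censoring (latencies ≥ 9 s are
  unobservable), which biases μ slightly downward when CV is large.
* The ANOVA assumes a complete grid and applies no sphericity
  correction; with many time levels and few subjects the uncorrected
  within-subject p-values are anticonservative.
* The circadian model is a single stationary sinusoid; it cannot express
  ultradian components or period drift.
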