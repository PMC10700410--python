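# Methods

## The model

`stopdrive` analyses a rapid motor-control task in which a participant
drives a simulated car from a start position to a stop sign and must stay
stopped there, with position and velocity recorded at every frame
(~60 Hz).  Behavior on each trial is summarized by a
proportional–derivative (PD) control law: the commanded acceleration is

    a(t) = K_p · (g − x(t)) − K_d · v(t)

where `g` is the stop-sign position, `K_p` (1/s²) is a *drive* gain that
accelerates toward the goal in proportion to the remaining distance, and
`K_d` (1/s) is a *damping* gain that decelerates in proportion to current
velocity, analogous to friction.  In the goal error `e = g − x` this is a
damped harmonic oscillator, `ë + K_d ė + K_p e = 0`, and the damping ratio
`ζ = K_d / (2√K_p)` cleanly separates regimes: `ζ < 1` overshoots the
sign, `ζ ≥ 1` approaches it monotonically.  Low `K_p` is interpreted as
proactive inhibitory control (restraining the initial drive), high `K_d`
as reactive inhibitory control (braking in response to incoming velocity
information).

Coordinates are normalized: start at 0, stop sign at `track_length = 1`.
The default speed cap is `max_speed = 1/0.75` so a car at full speed
traverses the track in 0.75 s, the task's speed-calibration constant.
Trials last 10 s at 60 samples/s (600 frames); a session is two blocks of
10 trials.

## Simulation

`simulate_trial` integrates the double integrator by explicit Euler at
the task's own frame interval `dt = 1/sample_rate`:

    a_i = K_p (g − x_i) − K_d v_i + ε_i,   ε_i ~ N(0, noise_sd²)
    x_{i+1} = x_i + v_i dt
    v_{i+1} = v_i + a_i dt

Euler at the recording rate is deliberate: the regression below is fit on
frame-sampled data, and this discretization makes the forward-difference
velocity derivative reproduce the regression equation exactly, so
parameter recovery is exact in the noiseless case and the noisy
regression is correctly specified.  Gains that put Euler past its
stability bound at the chosen `dt` raise an error rather than producing
divergent traces.  Velocity clipping at `±max_speed` exists but is off by
default — saturated samples violate the linear model and would bias fits.

`closed_form_trajectory` evaluates the exact solution of the noiseless
ODE (under-, critically- and over-damped branches selected by the sign of
`K_d² − 4K_p`, with near-critical discriminants folded into the critical
branch to avoid cancellation).  It is validated against a tight-tolerance
Runge–Kutta integration and serves as the simulator's oracle.

**Integrator accuracy.**  Explicit Euler is first order: over a gain grid
with `ζ ∈ [0.3, 2]` and `K_p ≤ 25`, the worst position error against the
closed form is ≈5×10⁻³ track lengths at `dt = 1/600` and falls below
1×10⁻³ at `dt ≈ 1/3600` (error halves with each halving of `dt`).  A
second-order integrator would be far closer to the ODE but would break
the exactness of the frame-rate regression (biasing noiseless recovery by
3–17% over the same grid); faithfulness to the estimator was preferred to
faithfulness to the continuum limit.

## Per-trial estimation

Acceleration is not recorded; it is derived by forward differences of
recorded velocity, `a_i = (v_{i+1} − v_i)/dt`, aligned to sample `i` (the
final sample drops out).  Velocity differencing is used rather than
double position differencing because it amplifies noise less.  `K_p` and
`K_d` are the coefficients of a two-predictor, zero-intercept least
squares regression of that acceleration on the goal error `e_i = g − x_i`
and its derivative `ė_i = −v_i`.

Analyses use natural-log gains: the raw gains are right-skewed across
participants, and the generator draws them log-normally.  A fit is marked
invalid — with a reason code, never an exception that aborts a cohort —
when the trial was error-terminated, the design is degenerate (car at the
goal, motionless) or rank-deficient, or either coefficient is
non-positive (the log is then undefined).  Invalid trials are excluded
from session means; error-terminated trials still feed the error-count
index.

**Fit assessment.**  Each trial is re-simulated noise-free from its
recorded starting position and velocity with the fitted gains, and
`R² = 1 − SS_res/SS_tot` between predicted and observed per-sample
velocity measures the variance in velocity the two-parameter model
explains.  `R²` may be negative when the simulation predicts worse than
the observed mean.

**Finite-sample bias.**  The regressors are predetermined (functions of
past noise), so per-trial OLS is consistent but not exactly unbiased —
the familiar dynamic-regression (Hurwicz) bias.  Measured at
`K_p = 6, K_d = 4` with 600 samples, the relative bias grows roughly
quadratically with the noise SD: ~0.1% at `noise_sd = 0.5`, ~0.7% at 1.0,
~3.5% at the default cohort noise 3.5.  It is a common multiplicative
shift across subjects, so the log-scale reliability and association
analyses are essentially unaffected; tests assert 3-SE unbiasedness in
the moderate-noise regime and a <5% bias bound at full cohort noise.

**Session summaries.**  Per subject × session: mean log `K_p` and log
`K_d` over valid trials, the mean final car position over completed
trials, the count of error-terminated trials and `log(count + 1)` (the
offset keeps zero-error subjects defined).  Sessions with no valid trial
are flagged missing.  An optional post-stop truncation (cutting each
trace one second after the car is durably stopped at the sign) is
available but off by default; the default fits the full 10-s trace.

## Reliability

Split-half reliability: within a session each subject's valid trials are
split odd/even (by nominal trial-index parity) or first/second half (by
rank among valid trials; an odd count puts the middle trial in the first
half), and the Pearson correlation across subjects between half means is
reported per parameter and session.  Fisher's z transformation,
`z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))`, compares the two
sessions' split-half correlations.

Test–retest reliability across sessions is ICC(3,1) — two-way mixed
model, consistency form, single fixed rater, with sessions as raters:

    ICC = (MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error), k = 2

assembled directly from the two-way ANOVA mean squares and checked in the
test suite against both a hand-built ANOVA oracle and pingouin's
`ICC(C,1)`.  The p-value comes from the between-subjects F test
`MS_subjects/MS_error` on `(n−1, (n−1)(k−1))` degrees of freedom (the
consistency form guarantees a fixed session offset does not reduce the
ICC).  Sensitivity toggles exclude subjects flagged as same-day
completers or non-mobile-device users.

## Association models

Covariate models are ordinary least squares with every variable — outcome
and predictors, binaries included — z-scored before fitting, so
coefficients are standardized betas (partial-standardization conventions
that leave binaries raw will differ by a constant factor per binary).
The model grid: outcomes {mean log `K_p`, mean log `K_d`, mean final
position, log error-trial count} each on {fear score, age, male gender,
bachelor's-or-higher education}, plus demographics-only variants for the
two log gains — six models.  Missing covariates are listwise-deleted, and
no multiple-testing correction is applied (the result table records the
number of models fitted).  With a single predictor the standardized beta
equals the Pearson correlation, which the tests exploit.

## Synthetic cohorts

The generator provides ground truth for every downstream stage.  Subject
level: `(log K_p, log K_d)` bivariate normal (means `ln 6`, `ln 4`; SDs
0.5, 0.4; correlation 0.5), with each subject's session-specific values
correlated across the two sessions at 0.85 (day-to-day policy drift), and
a planted standardized effect of the (cohort-standardized) fear score of
−0.3 on both log gains, residual variance rescaled so marginal SDs are
preserved.  The implied cross-session correlation of the true gains is
`β² + (1 − β²)ρ ≈ 0.86`.  Covariates follow the validation sample's mix:
fear ≈ truncated-normal(11, 4) on the instrument range 6–30, age ≈
truncated-normal(36, 9.5) on 18–70, 64% male, 78.7% bachelor's-or-higher,
~90% mobile-device, ~10% same-day completers.

Trial level: the gains jitter from trial to trial on the log scale (SDs
0.5 for `K_p`, 0.45 for `K_d`).  This within-session policy drift is
essential realism: with 600 samples per trial the regression pins each
trial's gains so precisely that, without it, split-half reliability is
~1.0 regardless of motor noise.  The jitter SDs were set via the
Spearman–Brown relation to produce split-half reliabilities around
0.8–0.9, and the motor-noise SD (3.5) so the cohort mean simulation `R²`
is ≈0.7 — the regimes real data exhibit.  Jitter draws past the Euler
stability bound (`K_p dt ≥ 0.95 K_d`, a deep tail) are redrawn.

Error-terminated trials arise endogenously when a trace crosses the
off-screen limit (truncated at that frame) and exogenously at a 5%
injection rate (truncated at a random frame after the first second),
standing in for thumb lifts and end-of-trial misses.  The task's
end-of-trial tolerance rule is deliberately not simulated: under white
acceleration noise it would terminate 15–45% of trials — a strong,
parameter-correlated selection unlike real subjects, who correct actively
near the sign.

All randomness flows from one integer seed through named substreams
(cohort, noise, error-trials), so stages reproduce independently and runs
are bit-deterministic.

**What passing tests do and do not show.**  The generator matches the
analysis pipeline's assumptions by construction (log-normal gains, linear
PD dynamics, white motor noise, ignorable error trials).  Passing
recovery and closure tests therefore demonstrate the *machinery* is
correct and calibrated, not that real thumb-on-screen data obey a linear
PD law; real data bring input nonlinearities, correlated noise,
device/frame-rate heterogeneity and learning effects the generator does
not model.

## Numerical choices and problem sizes

- Euler stability is enforced (`|1 + λ dt| ≤ 1` for both system
  eigenvalues) at simulation time; degenerate fits return reason codes.
- Closed-form branches switch on `|K_d² − 4K_p|` relative to scale
  (1e-12) to dodge cancellation near critical damping.
- Trajectory CSVs are written with repr-precision floats and re-read with
  the round-trip parser, so write→read is bit-exact.
- Test and acceptance problem sizes are desk scale by design: the default
  cohort is 100 subjects × 2 sessions × 20 trials (4,000 trajectories,
  ~6 s to generate and fit); association recovery uses 500 subjects ×
  1 session; calibration checks use 400–2,000 replicates.

## Known limitations

- The continuum-limit accuracy of the simulator is first order; analyses
  needing sub-milli-track accuracy at 600 Hz should use the closed form.
- The per-trial estimator's finite-sample bias (above) is visible at high
  motor noise; between-subject comparisons are unaffected.
- Whether the real task maps thumb displacement to velocity or
  acceleration is unresolved; the model treats acceleration as the
  controlled quantity throughout.
- Error-trial handling (exclusion from fitting, `log(count+1)`) is a
  convention; the original analysis's handling of restarts is unstated.
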