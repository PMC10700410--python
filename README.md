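# stopdrive

Proportional–derivative (PD) control modelling of a rapid stop-sign
driving task: simulate trajectories, estimate per-trial control gains,
and run the reliability and covariate-association analyses the task is
used for.

## The problem

Many behavioral measures of inhibitory control rest on one button press
per trial and show poor test–retest reliability.  An alternative is a
continuous task: drive a simulated car to a stop sign and stay stopped,
recording position and velocity at every frame (~60 Hz, so one 10-s
trial yields ~600 data points).  Each trial is summarized by a PD control
law,

&nbsp;&nbsp;&nbsp;&nbsp; *a(t) = K_p (g − x(t)) − K_d v(t)*,

with drive gain *K_p* (acceleration toward the goal per unit distance —
lower values read as proactive inhibitory control) and damping gain
*K_d* (braking per unit velocity, like friction — higher values read as
reactive inhibitory control).  *K_p* and *K_d* are estimated per trial by
zero-intercept least squares of finite-difference acceleration on the
goal error and its derivative; fits are assessed by re-simulating each
trial from its starting conditions and computing the *R²* between
simulated and observed velocity.  Log gains feed split-half reliability
(odd/even and first/second-half splits, compared across sessions by
Fisher's *z*), test–retest ICC(3,1) across two sessions, and
standardized-beta regressions on self-reported fear, age, gender and
education.

Because no raw dataset is bundled, the package includes a fully seeded
synthetic-cohort generator with known ground truth (log-normal gains,
session-to-session and trial-to-trial variability, planted fear effects,
error-terminated trials) so every stage is testable end to end.  It is
aimed at researchers in computational psychiatry and motor control who
want the analysis machinery, its calibration checks, or realistic
synthetic cohorts.

## Worked example

```python
import stopdrive as sd

config = sd.TaskConfig()                      # stop sign at 1.0, 60 Hz, 10 s trials
spec = sd.CohortSpec(n_subjects=40, seed=7)   # 2 sessions x 20 trials each
cohort = sd.sample_cohort(spec)
trajs = sd.generate_cohort_trajectories(cohort, config, spec)
fits_frame = sd.fits_to_frame(sd.fit_trajectories(trajs, config))

valid = fits_frame[fits_frame["valid"]]
print(f"fitted {len(fits_frame)} trials, {len(valid)} valid")
print(f"mean simulation R^2 = {valid['r_squared_sim'].mean():.2f}")

from stopdrive.reliability import format_report
print(format_report(sd.reliability_report(fits_frame, cohort)))
```

prints

```
fitted 1600 trials, 1435 valid
mean simulation R^2 = 0.72
Reliability report
============================================================
split-half  odd_even      log_k_p  session 1: r = +0.919 (n = 40, p = 5.9e-17)
split-half  odd_even      log_k_d  session 1: r = +0.819 (n = 40, p = 1.1e-10)
split-half  odd_even      log_k_p  session 2: r = +0.945 (n = 40, p = 4.1e-20)
split-half  odd_even      log_k_d  session 2: r = +0.813 (n = 40, p = 1.9e-10)
split-half  first_second  log_k_p  session 1: r = +0.887 (n = 40, p = 2.5e-14)
split-half  first_second  log_k_d  session 1: r = +0.754 (n = 40, p = 2e-08)
split-half  first_second  log_k_p  session 2: r = +0.928 (n = 40, p = 6.5e-18)
split-half  first_second  log_k_d  session 2: r = +0.816 (n = 40, p = 1.4e-10)
Fisher z    odd_even      log_k_p  s1 vs s2 : z = -0.878 (p = 0.38)
Fisher z    odd_even      log_k_d  s1 vs s2 : z = +0.077 (p = 0.94)
Fisher z    first_second  log_k_p  s1 vs s2 : z = -1.020 (p = 0.31)
Fisher z    first_second  log_k_d  s1 vs s2 : z = -0.708 (p = 0.48)
ICC(3,1)                  log_k_p  sessions : ICC = +0.883 (n = 40, p = 1.2e-14)
ICC(3,1)                  log_k_d  sessions : ICC = +0.822 (n = 40, p = 2.3e-11)
```

Read: within each session, mean log gains estimated from disjoint halves
of the trials correlate ~.75–.95 across subjects (high internal
consistency); the Fisher-z rows show neither parameter's split-half
reliability differs detectably between sessions; and the subject-level
mean log gains correlate ~.8–.9 across sessions run on different days
(high test–retest reliability).  The mean *R²* says the two fitted gains
alone reproduce ~70% of the variance in observed velocity.

The same pipeline runs from the shell and composes through documented
CSV layouts:

```bash
stopdrive simulate --seed 7 --n-subjects 40 --out sim/
stopdrive fit --trajectories sim/trajectories.csv --out fit/
stopdrive reliability --parameters fit/parameters.csv --out rel/
stopdrive associate --summaries fit/session_summaries.csv \
    --covariates sim/covariates.csv --out assoc/
stopdrive all --seed 7 --out run/          # everything, plus trace plots
```

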