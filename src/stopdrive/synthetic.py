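"""Synthetic cohorts with known ground truth.

Generates what the analysis pipeline assumes real data look like: subjects
whose log K_p and log K_d are bivariate normal across the cohort (the raw
gains are right-skewed, hence log-normal), correlated between the two
sessions; a planted negative standardized effect of the fear score on both
log gains; covariates with the validation sample's demographic mix; and,
per subject x session x trial, a noisy PD trajectory with occasional
error-terminated (truncated) trials.

All randomness flows from a single integer seed through named substreams
(cohort sampling vs. trajectory noise vs. error-trial placement), so each
stage is independently reproducible and runs are bit-deterministic.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .task import PDParams, TaskConfig, TrialTrajectory, simulate_trial

__all__ = ["CohortSpec", "sample_cohort", "generate_cohort_trajectories", "substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random stream derived from one top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    )


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a synthetic two-session cohort.

    Subject-level log gains: ``log k ~ Normal(mean, sd)`` with
    between-parameter correlation ``param_corr``; each subject's
    session-specific values correlate across sessions at ``session_corr``
    (day-to-day drift in control policy) and jitter from trial to trial
    with SD ``trial_sd_log_k_*`` (within-session policy drift; without it
    600-sample trials pin the gains so precisely that split-half
    reliability sits at ~1, unlike real behavior).  ``fear_effect_*`` are planted
    standardized effects: a subject one (fear) SD above the mean is
    shifted by ``effect * sd_log_k`` on that log gain, with residual
    variance rescaled so the marginal SD is preserved.  ``noise_sd`` is
    the within-trial motor-noise SD on acceleration (track units/s^2).

    Defaults describe a desk-scale cohort (100 subjects, 2 sessions of
    two 10-trial blocks) with the validation sample's demographic mix.
    """

    n_subjects: int = 100
    mean_log_k_p: float = math.log(6.0)
    sd_log_k_p: float = 0.5
    mean_log_k_d: float = math.log(4.0)
    sd_log_k_d: float = 0.4
    param_corr: float = 0.5
    session_corr: float = 0.85
    trial_sd_log_k_p: float = 0.5
    trial_sd_log_k_d: float = 0.45
    noise_sd: float = 3.5
    fear_effect_log_k_p: float = -0.3
    fear_effect_log_k_d: float = -0.3
    fear_mean: float = 11.0
    fear_sd: float = 4.0
    fear_range: tuple[float, float] = (6.0, 30.0)
    age_mean: float = 36.0
    age_sd: float = 9.5
    age_range: tuple[float, float] = (18.0, 70.0)
    p_male: float = 0.64
    p_bachelor_plus: float = 0.787
    p_mobile: float = 0.90
    p_same_day: float = 0.10
    error_rate: float = 0.05
    trials_per_session: int = 20
    trials_per_block: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in (
            "sd_log_k_p",
            "sd_log_k_d",
            "trial_sd_log_k_p",
            "trial_sd_log_k_d",
            "noise_sd",
            "fear_sd",
            "age_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("param_corr", "session_corr"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in ("fear_effect_log_k_p", "fear_effect_log_k_d"):
            value = getattr(self, name)
            if not (math.isfinite(value) and abs(value) <= 1.0):
                raise ValueError(f"{name} must be finite with |effect| <= 1")
        for name in ("p_male", "p_bachelor_plus", "p_mobile", "p_same_day", "error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.trials_per_session < 1 or self.trials_per_block < 1:
            raise ValueError("trial counts must be >= 1")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bivariate(rng: np.random.Generator, corr: float, size: int) -> np.ndarray:
    cov = np.array([[1.0, corr], [corr, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=size, method="cholesky")


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw subject-level ground truth: covariates and per-session gains.

    The session-s log gain of subject i is

        mu + beta * sd * z_fear_i
           + sd * sqrt(1 - beta^2) * (sqrt(rho) * c_i + sqrt(1 - rho) * e_is)

    with ``c`` a stable subject component and ``e_is`` session-specific,
    both bivariate across the two gains at ``param_corr``; ``z_fear`` is
    the cohort-standardized fear score.  Marginal SDs equal the spec SDs
    and the cross-session correlation is ``beta^2 + (1 - beta^2) * rho``.

    Returns one row per subject with covariates and
    ``true_log_k_{p,d}_s{1,2}`` columns.
    """
    seed = spec.seed if seed is None else seed
    rng = substream(seed, "cohort")
    n = spec.n_subjects

    fear = _truncated_normal(rng, spec.fear_mean, spec.fear_sd, *spec.fear_range, size=n)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n)
    gender_male = (rng.random(n) < spec.p_male).astype(int)
    education = (rng.random(n) < spec.p_bachelor_plus).astype(int)
    mobile = (rng.random(n) < spec.p_mobile).astype(int)
    same_day = (rng.random(n) < spec.p_same_day).astype(int)

    if n > 1 and fear.std(ddof=0) > 0:
        z_fear = (fear - fear.mean()) / fear.std(ddof=1)
    else:
        z_fear = np.zeros(n)

    common = _bivariate(rng, spec.param_corr, n)
    sess1 = _bivariate(rng, spec.param_corr, n)
    sess2 = _bivariate(rng, spec.param_corr, n)

    data: dict = {
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "fear": fear,
        "age": age,
        "gender_male": gender_male,
        "education_bachelor_plus": education,
        "device_mobile": mobile,
        "same_day_sessions": same_day,
    }
    rho = spec.session_corr
    specs = {
        "p": (spec.mean_log_k_p, spec.sd_log_k_p, spec.fear_effect_log_k_p, 0),
        "d": (spec.mean_log_k_d, spec.sd_log_k_d, spec.fear_effect_log_k_d, 1),
    }
    for tag, (mu, sd, beta, col) in specs.items():
        resid_scale = sd * math.sqrt(1.0 - beta * beta)
        base = mu + beta * sd * z_fear
        for session, eps in ((1, sess1), (2, sess2)):
            value = base + resid_scale * (
                math.sqrt(rho) * common[:, col] + math.sqrt(1.0 - rho) * eps[:, col]
            )
            data[f"true_log_k_{tag}_s{session}"] = value
    return pd.DataFrame(data)


def generate_cohort_trajectories(
    cohort: pd.DataFrame,
    config: TaskConfig,
    spec: CohortSpec,
    seed: int | None = None,
    sessions: tuple[int, ...] = (1, 2),
) -> list[TrialTrajectory]:
    """Simulate every trial of the cohort as a :class:`TrialTrajectory`.

    Each trial runs :func:`~stopdrive.task.simulate_trial` with the
    subject-session true gains, jittered per trial on the log scale by
    ``trial_sd_log_k_*``, plus the spec's motor-noise SD.  Jitter draws
    that would push the gains past the explicit-Euler stability bound at
    the task frame rate (``k_p * dt >= k_d``, a deep tail of the default
    distributions) are redrawn so the generator never emits a divergent
    trace.

    Error-terminated trials arise two ways, both flagged and excluded
    from fitting downstream: the task's off-screen rule (the car driven
    past ``offscreen_limit`` beyond the sign — truncated at that frame),
    and random terminations injected at rate ``error_rate`` (standing in
    for thumb lifts and end-of-trial misses), truncated at a random frame
    after the first second.  The task's end-of-trial tolerance rule is
    *not* simulated: under white acceleration noise it would fire far
    more often than for real subjects, who correct actively near the
    sign.  ``restart_count`` is a small Poisson count of within-trial
    restarts.
    """
    noise_rng = substream(spec.seed if seed is None else seed, "noise")
    error_rng = substream(spec.seed if seed is None else seed, "error-trials")

    n_frames = config.n_samples
    trajs: list[TrialTrajectory] = []
    for row in cohort.itertuples(index=False):
        for session in sessions:
            log_k_p = getattr(row, f"true_log_k_p_s{session}")
            log_k_d = getattr(row, f"true_log_k_d_s{session}")
            for trial in range(1, spec.trials_per_session + 1):
                for _ in range(100):
                    k_p = math.exp(log_k_p + spec.trial_sd_log_k_p * noise_rng.standard_normal())
                    k_d = math.exp(log_k_d + spec.trial_sd_log_k_d * noise_rng.standard_normal())
                    if k_p / config.sample_rate < 0.95 * k_d:
                        break
                else:  # pragma: no cover - unreachable under sane specs
                    k_p, k_d = math.exp(log_k_p), math.exp(log_k_d)
                traj = simulate_trial(
                    PDParams(k_p=k_p, k_d=k_d),
                    config,
                    noise_sd=spec.noise_sd,
                    seed=noise_rng,
                    subject_id=row.subject_id,
                    session=session,
                    block=1 + (trial - 1) // spec.trials_per_block,
                    trial_index=trial,
                )
                traj.restart_count = int(error_rng.poisson(0.2))
                offscreen = np.nonzero(traj.position > config.goal + config.offscreen_limit)[0]
                if offscreen.size:
                    cut = max(3, int(offscreen[0]))
                    traj.t = traj.t[:cut]
                    traj.position = traj.position[:cut]
                    traj.velocity = traj.velocity[:cut]
                    traj.terminated_with_error = True
                if error_rng.random() < spec.error_rate and not traj.terminated_with_error:
                    cut = int(
                        error_rng.integers(
                            min(n_frames - 1, round(config.sample_rate)), n_frames
                        )
                    )
                    traj.t = traj.t[:cut]
                    traj.position = traj.position[:cut]
                    traj.velocity = traj.velocity[:cut]
                    traj.terminated_with_error = True
                trajs.append(traj)
    return trajs
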