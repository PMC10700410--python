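"""Per-trial PD parameter estimation and session-level aggregation.

Acceleration is not recorded by the task, so it is derived by forward
finite differences of the recorded velocity: ``a_i = (v_{i+1} - v_i) / dt``,
aligned to sample ``i`` (the last sample drops out).  K_p and K_d are then
the coefficients of a two-predictor, zero-intercept least-squares
regression of that acceleration on the goal error ``e_i = goal - x_i`` and
its derivative ``-v_i``.

Goodness of fit is assessed by forward simulation: the trial is re-simulated
(noise-free) from its recorded starting conditions with the fitted gains,
and the R^2 between the simulated and observed velocity series is reported
as the variance in velocity explained by the two-parameter model.

Analyses downstream use natural-log gains (the gains are right-skewed
across subjects); fits whose coefficients are non-positive, or whose design
matrix is degenerate, are marked invalid with a reason code rather than
aborting the pipeline, and are excluded from session means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import PDParams, TaskConfig, TrialTrajectory

__all__ = [
    "PDFit",
    "SessionSummary",
    "estimate_derivatives",
    "fit_trial_pd",
    "assess_fit",
    "predict_velocity",
    "summarize_session",
    "fit_trajectories",
    "fits_to_frame",
    "summaries_to_frame",
]

# reason codes for invalid fits
REASON_OK = ""
REASON_ERROR_TRIAL = "error_trial"
REASON_DEGENERATE = "degenerate"
REASON_RANK_DEFICIENT = "rank_deficient"
REASON_NONPOSITIVE = "nonpositive_coefficient"
REASON_TOO_SHORT = "too_few_samples"


@dataclass
class PDFit:
    """Fitted gains for one trial, with goodness-of-fit diagnostics.

    ``valid`` is True only when both coefficients are positive and finite
    (so the logs exist); otherwise ``reason`` names the failure and the log
    fields are NaN.  ``r_squared_sim`` may be negative when the forward
    simulation predicts velocity worse than its mean.
    """

    subject_id: str
    session: int
    block: int
    trial_index: int
    k_p: float = math.nan
    k_d: float = math.nan
    log_k_p: float = math.nan
    log_k_d: float = math.nan
    r_squared_sim: float = math.nan
    n_samples_used: int = 0
    valid: bool = False
    reason: str = REASON_OK


@dataclass
class SessionSummary:
    """Per-subject, per-session parameter means and behavioral indices.

    Parameter means are over valid trials only.  ``final_position_mean``
    averages the last recorded car position of completed (non-error)
    trials; ``log_error_trial_count`` is ``log(count + 1)`` so zero-error
    subjects remain defined.  ``missing`` flags subjects with no valid
    trial in the session.
    """

    subject_id: str
    session: int
    mean_log_k_p: float = math.nan
    mean_log_k_d: float = math.nan
    n_valid_trials: int = 0
    final_position_mean: float = math.nan
    error_trial_count: int = 0
    log_error_trial_count: float = math.nan
    missing: bool = False


def estimate_derivatives(traj: TrialTrajectory) -> np.ndarray:
    """Acceleration by forward differences of recorded velocity.

    Returns ``(v[1:] - v[:-1]) / (t[1:] - t[:-1])``, aligned to ``t[:-1]``
    — the same alignment the PD regression uses for its predictors.

    Raises
    ------
    ValueError
        On fewer than 3 samples or non-increasing (duplicate) time stamps.
    """
    if len(traj) < 3:
        raise ValueError(f"need >= 3 samples to estimate derivatives, got {len(traj)}")
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing time stamps")
    return np.diff(traj.velocity) / dt


def fit_trial_pd(
    traj: TrialTrajectory,
    config: TaskConfig,
    *,
    assess: bool = True,
    include_error_trials: bool = False,
) -> PDFit:
    """Estimate K_p and K_d for one trial by zero-intercept least squares.

    Regresses finite-difference acceleration on the goal error
    ``e_i = goal - x_i`` and its derivative ``-v_i`` (both aligned to
    ``t[:-1]``), with no intercept.  The error coefficient is K_p and the
    error-derivative coefficient is K_d.

    Error-terminated trials, degenerate trajectories (car at the goal and
    motionless throughout), rank-deficient designs and non-positive
    coefficients yield an invalid :class:`PDFit` with a reason code — never
    an exception that aborts a cohort fit.  When ``assess`` is true and the
    fit is valid, :func:`assess_fit` fills ``r_squared_sim``.
    """
    fit = PDFit(
        subject_id=traj.subject_id,
        session=traj.session,
        block=traj.block,
        trial_index=traj.trial_index,
    )
    if traj.terminated_with_error and not include_error_trials:
        fit.reason = REASON_ERROR_TRIAL
        return fit
    if len(traj) < 3:
        fit.reason = REASON_TOO_SHORT
        return fit

    accel = estimate_derivatives(traj)
    err = config.goal - traj.position[:-1]
    err_dot = -traj.velocity[:-1]
    fit.n_samples_used = len(accel)

    scale = max(np.max(np.abs(err)), np.max(np.abs(err_dot)))
    if scale < 1e-12:
        fit.reason = REASON_DEGENERATE
        return fit

    design = np.column_stack([err, err_dot])
    coef, _, rank, _ = np.linalg.lstsq(design, accel, rcond=None)
    if rank < 2:
        fit.reason = REASON_RANK_DEFICIENT
        return fit

    fit.k_p, fit.k_d = float(coef[0]), float(coef[1])
    if not (fit.k_p > 0 and fit.k_d > 0 and math.isfinite(fit.k_p) and math.isfinite(fit.k_d)):
        fit.reason = REASON_NONPOSITIVE
        return fit

    fit.log_k_p = math.log(fit.k_p)
    fit.log_k_d = math.log(fit.k_d)
    fit.valid = True
    if assess:
        fit.r_squared_sim = assess_fit(traj, fit, config)
    return fit


def predict_velocity(
    traj: TrialTrajectory, k_p: float, k_d: float, config: TaskConfig
) -> np.ndarray:
    """Noise-free forward-simulated velocity from the trial's start state.

    Steps explicit Euler with the given gains over the trial's own time
    stamps, starting from its recorded initial position and velocity.
    """
    t = traj.t
    n = len(t)
    goal = config.goal
    x = traj.position[0]
    v = traj.velocity[0]
    v_pred = np.empty(n)
    v_pred[0] = v
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        a = k_p * (goal - x) - k_d * v
        x = x + v * dt
        v = v + a * dt
        v_pred[i + 1] = v
    return v_pred


def assess_fit(traj: TrialTrajectory, fit: PDFit, config: TaskConfig) -> float:
    """R^2 of observed velocity against the forward-simulated prediction.

    Re-simulates the trial noise-free from its recorded initial position
    and velocity using the fitted gains, then returns
    ``1 - SS_residual / SS_total`` over the per-sample velocity.
    """
    if not fit.valid:
        raise ValueError(f"cannot assess an invalid fit (reason={fit.reason!r})")
    v_pred = predict_velocity(traj, fit.k_p, fit.k_d, config)
    v_obs = traj.velocity
    ss_tot = float(np.sum((v_obs - v_obs.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    ss_res = float(np.sum((v_obs - v_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def summarize_session(
    fits: list[PDFit],
    trajs: list[TrialTrajectory],
) -> SessionSummary:
    """Aggregate one subject-session: mean log gains and behavioral indices.

    All fits (and trajectories) must belong to a single subject and
    session.  Parameter means use valid fits only; the final-position index
    averages the last sample of completed trials; the error-trial count is
    the number of error-terminated trajectories, reported alongside
    ``log(count + 1)``.  With zero valid trials the summary is flagged
    ``missing`` (parameter means NaN) rather than raising.
    """
    if not fits:
        raise ValueError("summarize_session requires at least one fit")
    keys = {(f.subject_id, f.session) for f in fits} | {
        (tr.subject_id, tr.session) for tr in trajs
    }
    if len(keys) != 1:
        raise ValueError(f"fits/trajectories span multiple subject-sessions: {sorted(keys)}")
    subject_id, session = next(iter(keys))

    valid = [f for f in fits if f.valid]
    completed = [tr for tr in trajs if not tr.terminated_with_error and len(tr)]
    n_errors = sum(tr.terminated_with_error for tr in trajs)

    summary = SessionSummary(
        subject_id=subject_id,
        session=session,
        n_valid_trials=len(valid),
        error_trial_count=n_errors,
        log_error_trial_count=math.log(n_errors + 1),
    )
    if completed:
        summary.final_position_mean = float(
            np.mean([tr.position[-1] for tr in completed])
        )
    if valid:
        summary.mean_log_k_p = float(np.mean([f.log_k_p for f in valid]))
        summary.mean_log_k_d = float(np.mean([f.log_k_d for f in valid]))
    else:
        summary.missing = True
    return summary


# --------------------------------------------------------------------------
# Cohort-level conveniences
# --------------------------------------------------------------------------

def fit_trajectories(
    trajs: list[TrialTrajectory], config: TaskConfig, *, assess: bool = True
) -> list[PDFit]:
    """Fit every trajectory; error trials yield invalid fits, 1:1 with input."""
    return [fit_trial_pd(tr, config, assess=assess) for tr in trajs]


def fits_to_frame(fits: list[PDFit]) -> pd.DataFrame:
    """Parameter table: one row per trial fit."""
    return pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in fits],
            "session": [f.session for f in fits],
            "block": [f.block for f in fits],
            "trial": [f.trial_index for f in fits],
            "k_p": [f.k_p for f in fits],
            "k_d": [f.k_d for f in fits],
            "log_k_p": [f.log_k_p for f in fits],
            "log_k_d": [f.log_k_d for f in fits],
            "r_squared_sim": [f.r_squared_sim for f in fits],
            "n_samples_used": [f.n_samples_used for f in fits],
            "valid": [f.valid for f in fits],
            "reason": [f.reason for f in fits],
        }
    )


def summaries_to_frame(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Session-summary table: one row per subject x session."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "session": [s.session for s in summaries],
            "mean_log_k_p": [s.mean_log_k_p for s in summaries],
            "mean_log_k_d": [s.mean_log_k_d for s in summaries],
            "n_valid_trials": [s.n_valid_trials for s in summaries],
            "final_position_mean": [s.final_position_mean for s in summaries],
            "error_trial_count": [s.error_trial_count for s in summaries],
            "log_error_trial_count": [s.log_error_trial_count for s in summaries],
            "missing": [s.missing for s in summaries],
        }
    )
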