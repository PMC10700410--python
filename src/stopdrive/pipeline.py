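"""File I/O, pipeline configuration and the end-to-end analysis run.

The pipeline composes the stages simulate-or-read -> fit -> summarize ->
reliability -> association -> trace report, each reading and writing the
documented CSV layouts so stages can also be run (and re-run) separately.

Trajectory CSV layout (one row per frame, header required, UTF-8):
``subject_id, session, block, trial, t, position, velocity,
terminated_with_error, restart_count``.  Floats are written with pandas'
round-trip repr, so read-after-write reproduces the numeric fields
exactly.

Covariate CSV layout (one row per subject): ``subject_id, fear, age,
gender_male, education_bachelor_plus, device_mobile, same_day_sessions``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import results_to_frame, run_association_suite
from .fitting import (
    SessionSummary,
    fit_trajectories,
    fits_to_frame,
    predict_velocity,
    summaries_to_frame,
    summarize_session,
)
from .reliability import SplitScheme, format_report, reliability_report
from .synthetic import CohortSpec, generate_cohort_trajectories, sample_cohort
from .task import TaskConfig, TrialTrajectory

__all__ = [
    "PipelineConfig",
    "read_trajectories",
    "write_trajectories",
    "read_covariates",
    "write_covariates",
    "run_pipeline",
    "average_velocity_traces",
]

logger = logging.getLogger("stopdrive")

TRAJECTORY_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial",
    "t",
    "position",
    "velocity",
    "terminated_with_error",
    "restart_count",
]
COVARIATE_COLUMNS = [
    "subject_id",
    "fear",
    "age",
    "gender_male",
    "education_bachelor_plus",
    "device_mobile",
    "same_day_sessions",
]


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def write_trajectories(
    trajs: list[TrialTrajectory], path: str | Path, *, overwrite: bool = False
) -> Path:
    """Write trajectories to the standard frame-per-row CSV layout."""
    path = _output_path(path, overwrite)
    frames = [
        pd.DataFrame(
            {
                "subject_id": tr.subject_id,
                "session": tr.session,
                "block": tr.block,
                "trial": tr.trial_index,
                "t": tr.t,
                "position": tr.position,
                "velocity": tr.velocity,
                "terminated_with_error": int(tr.terminated_with_error),
                "restart_count": tr.restart_count,
            }
        )
        for tr in trajs
    ]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    table.to_csv(path, index=False)
    return path


def read_trajectories(path: str | Path) -> list[TrialTrajectory]:
    """Read the standard trajectory CSV into typed trajectories.

    Rows are grouped by (subject, session, block, trial).  A trial whose
    time stamps are not strictly increasing is rejected with a
    line-numbered warning while the remaining trials still load; missing
    columns raise.  An empty file (header only) yields an empty list with
    a warning.
    """
    path = Path(path)
    # round_trip parser: bit-exact re-read of the repr floats we write
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if table.empty:
        logger.warning("%s: no trajectory rows (header only)", path)
        return []

    trajs: list[TrialTrajectory] = []
    for key, grp in table.groupby(["subject_id", "session", "block", "trial"], sort=True):
        subject_id, session, block, trial = key
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(grp.index[np.argmin(np.diff(t) > 0)]) + 2  # +2: header + 1-based
            logger.warning(
                "%s: trial %s rejected: non-monotone time near line %d",
                path,
                key,
                bad,
            )
            continue
        trajs.append(
            TrialTrajectory(
                subject_id=str(subject_id),
                session=int(session),
                block=int(block),
                trial_index=int(trial),
                t=t,
                position=grp["position"].to_numpy(dtype=float),
                velocity=grp["velocity"].to_numpy(dtype=float),
                terminated_with_error=bool(grp["terminated_with_error"].iloc[0]),
                restart_count=int(grp["restart_count"].iloc[0]),
            )
        )
    return trajs


def write_covariates(
    covariates: pd.DataFrame, path: str | Path, *, overwrite: bool = False
) -> Path:
    path = _output_path(path, overwrite)
    covariates[COVARIATE_COLUMNS].to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return table


def _output_path(path: str | Path, overwrite: bool) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True (--overwrite) to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


# --------------------------------------------------------------------------
# Trace report (averaged observed vs simulated velocity)
# --------------------------------------------------------------------------

def average_velocity_traces(
    trajs: list[TrialTrajectory],
    fits_frame: pd.DataFrame,
    config: TaskConfig,
) -> pd.DataFrame:
    """Per-subject mean observed and fitted-simulated velocity traces.

    For every subject, averages across all full-length completed trials
    (both sessions) the observed velocity and the velocity re-simulated
    from each trial's own fitted gains — the model-fit picture of the
    cohort.  Returns long-format columns
    ``subject_id, t, observed, simulated``.
    """
    fit_lookup = {
        (r.subject_id, r.session, r.trial): (r.k_p, r.k_d)
        for r in fits_frame[fits_frame["valid"]].itertuples(index=False)
    }
    n_full = config.n_samples
    per_subject: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for tr in trajs:
        key = (tr.subject_id, tr.session, tr.trial_index)
        if tr.terminated_with_error or len(tr) != n_full or key not in fit_lookup:
            continue
        k_p, k_d = fit_lookup[key]
        per_subject.setdefault(tr.subject_id, []).append(
            (tr.velocity, predict_velocity(tr, k_p, k_d, config))
        )

    frames = []
    t = np.arange(n_full) * config.dt
    for subject, pairs in sorted(per_subject.items()):
        observed = np.mean([p[0] for p in pairs], axis=0)
        simulated = np.mean([p[1] for p in pairs], axis=0)
        frames.append(
            pd.DataFrame(
                {"subject_id": subject, "t": t, "observed": observed, "simulated": simulated}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["subject_id", "t", "observed", "simulated"])
    return pd.concat(frames, ignore_index=True)


def plot_traces(
    traces: pd.DataFrame,
    fits_frame: pd.DataFrame,
    path: str | Path,
    *,
    n_panels: int = 9,
) -> Path | None:
    """Panel plot of averaged observed vs simulated velocity.

    Subjects are picked at evenly spaced percentiles of mean fitted K_p
    (10th..90th for the default 9 panels), so the panels span the range
    of drive gains in the cohort.
    """
    if traces.empty:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_kp = (
        fits_frame[fits_frame["valid"]]
        .groupby("subject_id")["k_p"]
        .mean()
        .loc[lambda s: s.index.isin(traces["subject_id"].unique())]
        .sort_values()
    )
    n_panels = min(n_panels, len(mean_kp))
    percentiles = np.linspace(10, 90, n_panels)
    picks = [
        mean_kp.index[min(len(mean_kp) - 1, int(round(q / 100 * (len(mean_kp) - 1))))]
        for q in percentiles
    ]
    picks = list(dict.fromkeys(picks))

    ncols = 3
    nrows = math.ceil(len(picks) / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    for ax, subject in zip(axes.flat, picks):
        sub = traces[traces["subject_id"] == subject]
        ax.axis("on")
        ax.plot(sub["t"], sub["observed"], label="observed", lw=1.2)
        ax.plot(sub["t"], sub["simulated"], label="simulated", lw=1.2, ls="--")
        ax.set_title(f"{subject} (mean K_p={mean_kp[subject]:.1f})", fontsize=8)
        ax.set_xlabel("time (s)", fontsize=7)
        ax.set_ylabel("velocity", fontsize=7)
        ax.tick_params(labelsize=6)
    axes.flat[0].legend(fontsize=6)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


# --------------------------------------------------------------------------
# Pipeline configuration and run
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Either ``trajectories`` (a CSV path) or ``cohort_spec`` (simulate) must
    be given.  ``covariates`` is optional; without it the association stage
    and exclusion flags are unavailable.  Existing outputs are never
    silently overwritten — set ``overwrite``.
    """

    outdir: str | Path
    trajectories: str | Path | None = None
    covariates: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    task: TaskConfig = field(default_factory=TaskConfig)
    truncate_after_stop: bool = False
    exclude_same_day: bool = False
    exclude_non_mobile: bool = False
    schemes: tuple[SplitScheme, ...] = (SplitScheme.ODD_EVEN, SplitScheme.FIRST_SECOND)
    seed: int = 0
    overwrite: bool = False
    save_trajectories: bool = False
    make_plot: bool = True

    def __post_init__(self) -> None:
        if self.trajectories is None and self.cohort_spec is None:
            raise ValueError("provide either a trajectory CSV or a CohortSpec to simulate")
        for attr in ("trajectories", "covariates"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr} file not found: {value}")

    def config_hash(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (Path, SplitScheme)):
                return str(obj)
            raise TypeError(type(obj))

        payload = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def truncate_after_stop(traj: TrialTrajectory, config: TaskConfig) -> TrialTrajectory:
    """Optionally drop samples after the car has come to rest at the sign.

    Finds the earliest frame from which the car stays within
    ``goal_tolerance`` of the sign with |velocity| below 5% of max speed
    for the rest of the trial, and cuts one second after it (so the fit
    retains the arrival dynamics plus a short stopped segment).
    """
    at_goal = (np.abs(traj.position - config.goal) <= config.goal_tolerance) & (
        np.abs(traj.velocity) <= 0.05 * config.max_speed
    )
    # suffix-AND: stopped[i] true iff at_goal holds from i to the end
    stopped = np.logical_and.accumulate(at_goal[::-1])[::-1]
    if not stopped.any():
        return traj
    first = int(np.argmax(stopped))
    cut = min(len(traj), first + round(config.sample_rate))
    if cut < 3:
        return traj
    return TrialTrajectory(
        subject_id=traj.subject_id,
        session=traj.session,
        block=traj.block,
        trial_index=traj.trial_index,
        t=traj.t[:cut],
        position=traj.position[:cut],
        velocity=traj.velocity[:cut],
        terminated_with_error=traj.terminated_with_error,
        restart_count=traj.restart_count,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate-or-read -> fit -> summarize -> reliability ->
    association -> traces, writing the output bundle to ``config.outdir``.

    Returns a dict of the in-memory tables plus output paths.  Any stage
    failure halts with a stage-tagged error and the manifest marks the run
    incomplete.  Identical configs and seeds yield identical bundles
    (manifest timestamp aside).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = {
        "package": "stopdrive",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "complete": False,
    }
    outputs: dict = {"outdir": outdir}
    stage = "setup"
    try:
        # ---- simulate or read -------------------------------------------
        stage = "input"
        covariates = None
        if config.trajectories is not None:
            logger.info("reading trajectories from %s", config.trajectories)
            trajs = read_trajectories(config.trajectories)
            if config.covariates is not None:
                covariates = read_covariates(config.covariates)
        else:
            spec = config.cohort_spec
            logger.info(
                "simulating cohort: %d subjects, %d trials/session, seed %d",
                spec.n_subjects,
                spec.trials_per_session,
                config.seed,
            )
            cohort = sample_cohort(spec, seed=config.seed)
            trajs = generate_cohort_trajectories(cohort, config.task, spec, seed=config.seed)
            covariates = cohort[COVARIATE_COLUMNS]
            cohort.to_csv(_output_path(outdir / "cohort_truth.csv", config.overwrite), index=False)
            write_covariates(covariates, outdir / "covariates.csv", overwrite=config.overwrite)
            if config.save_trajectories:
                write_trajectories(
                    trajs, outdir / "trajectories.csv", overwrite=config.overwrite
                )
        if not trajs:
            raise ValueError("no trajectories to analyse")
        manifest["n_trajectories"] = len(trajs)

        # ---- fit ---------------------------------------------------------
        stage = "fit"
        fit_input = (
            [truncate_after_stop(tr, config.task) for tr in trajs]
            if config.truncate_after_stop
            else trajs
        )
        fits = fit_trajectories(fit_input, config.task)
        fits_frame = fits_to_frame(fits)
        fits_frame.to_csv(_output_path(outdir / "parameters.csv", config.overwrite), index=False)
        outputs["parameters"] = fits_frame
        logger.info(
            "fitted %d trials (%d valid)", len(fits), int(fits_frame["valid"].sum())
        )

        # ---- summarize ---------------------------------------------------
        stage = "summarize"
        summaries = []
        by_key: dict[tuple, tuple[list, list]] = {}
        for tr, fit in zip(trajs, fits):
            entry = by_key.setdefault((tr.subject_id, tr.session), ([], []))
            entry[0].append(fit)
            entry[1].append(tr)
        for (subject, session), (fit_group, traj_group) in sorted(by_key.items()):
            summaries.append(summarize_session(fit_group, traj_group))
        summary_frame = summaries_to_frame(summaries)
        summary_frame.to_csv(
            _output_path(outdir / "session_summaries.csv", config.overwrite), index=False
        )
        outputs["session_summaries"] = summary_frame

        # ---- reliability -------------------------------------------------
        stage = "reliability"
        n_subjects = fits_frame.loc[fits_frame["valid"], "subject_id"].nunique()
        if n_subjects < 4:
            logger.warning(
                "reliability stage skipped: insufficient subjects (%d < 4)", n_subjects
            )
            outputs["reliability"] = None
        else:
            report = reliability_report(
                fits_frame,
                covariates,
                exclude_same_day=config.exclude_same_day,
                exclude_non_mobile=config.exclude_non_mobile,
                schemes=config.schemes,
            )
            report.to_csv(_output_path(outdir / "reliability.csv", config.overwrite), index=False)
            (outdir / "reliability.txt").write_text(format_report(report))
            outputs["reliability"] = report

        # ---- association -------------------------------------------------
        stage = "association"
        if covariates is None:
            logger.warning("association stage skipped: no covariate table")
            outputs["association"] = None
        else:
            assoc_frames = []
            for session in sorted(summary_frame["session"].unique()):
                cohort_table = summary_frame[
                    (summary_frame["session"] == session) & (~summary_frame["missing"])
                ].merge(covariates, on="subject_id")
                if len(cohort_table) < MIN_ASSOCIATION_CASES:
                    logger.warning(
                        "association skipped for session %d: %d subjects",
                        session,
                        len(cohort_table),
                    )
                    continue
                results = run_association_suite(
                    cohort_table,
                    exclude_same_day=config.exclude_same_day,
                    exclude_non_mobile=config.exclude_non_mobile,
                )
                frame = results_to_frame(results)
                frame.insert(0, "session", session)
                assoc_frames.append(frame)
            if assoc_frames:
                assoc = pd.concat(assoc_frames, ignore_index=True)
                assoc.to_csv(_output_path(outdir / "association.csv", config.overwrite), index=False)
                outputs["association"] = assoc
            else:
                outputs["association"] = None

        # ---- traces ------------------------------------------------------
        stage = "traces"
        traces = average_velocity_traces(trajs, fits_frame, config.task)
        traces.to_csv(_output_path(outdir / "traces.csv", config.overwrite), index=False)
        outputs["traces"] = traces
        if config.make_plot and not traces.empty:
            plot_traces(traces, fits_frame, outdir / "traces.png")

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest
    return outputs


# minimum subjects for the 4-predictor standardized model (p + 2 cases)
MIN_ASSOCIATION_CASES = 6
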