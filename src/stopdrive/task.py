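"""Task geometry and proportional-derivative (PD) car dynamics.

The simulated task: a car starts at position 0 and must be driven to a stop
sign at position ``track_length`` and stay stopped there.  Under the PD
control model the commanded acceleration is

    a(t) = k_p * (goal - x(t)) - k_d * v(t) + noise

where ``k_p`` (drive gain, 1/s^2) accelerates toward the goal in proportion
to the remaining distance and ``k_d`` (damping gain, 1/s) decelerates in
proportion to the current velocity, like friction.  The noiseless system is
a damped harmonic oscillator in the goal error ``e = goal - x``; the
damping ratio ``k_d / (2 sqrt(k_p))`` determines whether the car overshoots
the sign (< 1) or approaches it monotonically (>= 1).

This module provides the discrete-time (explicit Euler) simulator used to
generate trajectories at the task's own frame rate, and the closed-form
solution of the linear ODE used as an analytic oracle for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "PDParams",
    "TrialTrajectory",
    "simulate_trial",
    "closed_form_trajectory",
    "damping_ratio",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Geometry, timing and speed constants of the driving task.

    Position is normalized so the start is 0 and the stop sign (the goal)
    is at ``track_length`` = 1.  The default ``max_speed`` is chosen so
    that a car moving at full speed traverses the track in 0.75 s, the
    task's speed-calibration constant.

    Parameters
    ----------
    track_length : float
        Distance from start to the stop sign (dimensionless track units).
    max_speed : float
        Speed cap, track units per second.  ``track_length / max_speed``
        is the nominal max-speed traversal time.
    sample_rate : float
        Recording rate in frames per second (the task records position and
        velocity every frame at ~60 Hz).
    trial_duration : float
        Length of one trial in seconds.
    goal_tolerance : float
        Distance from the sign within which the car must end the trial.
    offscreen_limit : float
        Distance past the sign at which a trial is terminated with error.
    """

    track_length: float = 1.0
    max_speed: float = 1.0 / 0.75
    sample_rate: float = 60.0
    trial_duration: float = 10.0
    goal_tolerance: float = 0.05
    offscreen_limit: float = 0.5

    def __post_init__(self) -> None:
        for name in ("track_length", "max_speed", "sample_rate", "trial_duration"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"TaskConfig.{name} must be finite and > 0, got {value!r}")
        if self.goal_tolerance < 0 or self.offscreen_limit <= 0:
            raise ValueError("goal_tolerance must be >= 0 and offscreen_limit > 0")

    @property
    def goal(self) -> float:
        """Goal (stop sign) position."""
        return self.track_length

    @property
    def dt(self) -> float:
        """Inter-frame interval in seconds."""
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        """Number of recorded frames in one full-length trial."""
        return round(self.trial_duration * self.sample_rate)

    @property
    def max_speed_traversal_time(self) -> float:
        """Time for a car at max speed to cross the whole track (s)."""
        return self.track_length / self.max_speed


@dataclass(frozen=True)
class PDParams:
    """PD controller gains: drive ``k_p`` (1/s^2) and damping ``k_d`` (1/s).

    Both gains must be strictly positive and finite — analyses work on the
    natural logs of the gains, so non-positive values are rejected here
    rather than silently propagated into the log transform.
    """

    k_p: float
    k_d: float

    def __post_init__(self) -> None:
        for name in ("k_p", "k_d"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"PDParams.{name} must be finite and > 0, got {value!r}")

    @property
    def log_k_p(self) -> float:
        return math.log(self.k_p)

    @property
    def log_k_d(self) -> float:
        return math.log(self.k_d)


@dataclass
class TrialTrajectory:
    """One trial's recorded time/position/velocity series.

    ``t`` starts at 0 and is strictly increasing; ``position`` and
    ``velocity`` are sampled per frame.  ``terminated_with_error`` marks
    trials ended by the task's restart rules (thumb lifted, car driven off
    screen, or car not stopped at the sign); such trials carry no usable
    parameter estimate but feed the error-count behavioral index.
    """

    subject_id: str
    session: int
    block: int
    trial_index: int
    t: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    terminated_with_error: bool = False
    restart_count: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (len(self.t) == len(self.position) == len(self.velocity)):
            raise ValueError("t, position and velocity must have equal length")
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if self.restart_count < 0:
            raise ValueError("restart_count must be >= 0")

    def __len__(self) -> int:
        return len(self.t)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _check_euler_stability(params: PDParams, dt: float) -> None:
    # Explicit Euler applied to e'' = -k_d e' - k_p e amplifies each
    # continuous eigenvalue lambda by |1 + lambda*dt| per step; require
    # both factors <= 1 so the discrete trajectory cannot diverge.
    disc = complex(params.k_d * params.k_d - 4.0 * params.k_p)
    root = disc ** 0.5
    for lam in ((-params.k_d + root) / 2.0, (-params.k_d - root) / 2.0):
        if abs(1.0 + lam * dt) > 1.0 + 1e-12:
            raise ValueError(
                f"explicit Euler unstable for k_p={params.k_p}, k_d={params.k_d} "
                f"at dt={dt:g}: growth factor {abs(1.0 + lam * dt):.4f} per step; "
                "increase sample_rate or reduce the gains"
            )


def simulate_trial(
    params: PDParams,
    config: TaskConfig,
    x0: float = 0.0,
    v0: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    *,
    clip_velocity: bool = False,
    subject_id: str = "sim",
    session: int = 1,
    block: int = 1,
    trial_index: int = 1,
) -> TrialTrajectory:
    """Simulate one trial of PD-controlled driving by explicit Euler.

    Integrates the double integrator at ``dt = 1/sample_rate``::

        a_i = k_p * (goal - x_i) - k_d * v_i + eps_i,   eps_i ~ N(0, noise_sd^2)
        x_{i+1} = x_i + v_i * dt
        v_{i+1} = v_i + a_i * dt

    for ``round(trial_duration * sample_rate)`` recorded samples.  The
    noise term models trial-to-trial motor noise as additive white noise on
    acceleration.  With ``clip_velocity=True`` the updated velocity is
    clipped to ``[-max_speed, +max_speed]``; clipping is off by default
    because saturated samples violate the linear PD model.

    Identical seeds yield bit-identical trajectories.

    Raises
    ------
    ValueError
        If ``noise_sd`` is negative or the gains put explicit Euler past
        its stability bound at this ``dt`` (divergent traces are reported,
        never silently produced).
    """
    if not (math.isfinite(noise_sd) and noise_sd >= 0):
        raise ValueError(f"noise_sd must be finite and >= 0, got {noise_sd!r}")
    if not (math.isfinite(x0) and math.isfinite(v0)):
        raise ValueError("x0 and v0 must be finite")
    _check_euler_stability(params, config.dt)

    n = config.n_samples
    dt = config.dt
    goal = config.goal
    k_p, k_d = params.k_p, params.k_d

    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, n - 1)
    else:
        eps = np.zeros(n - 1)

    x = np.empty(n)
    v = np.empty(n)
    x[0], v[0] = x0, v0
    vmax = config.max_speed
    for i in range(n - 1):
        a = k_p * (goal - x[i]) - k_d * v[i] + eps[i]
        x[i + 1] = x[i] + v[i] * dt
        v_next = v[i] + a * dt
        if clip_velocity:
            v_next = min(max(v_next, -vmax), vmax)
        v[i + 1] = v_next

    return TrialTrajectory(
        subject_id=subject_id,
        session=session,
        block=block,
        trial_index=trial_index,
        t=np.arange(n) * dt,
        position=x,
        velocity=v,
    )


# --------------------------------------------------------------------------
# Analytic oracle
# --------------------------------------------------------------------------

def closed_form_trajectory(
    params: PDParams,
    config: TaskConfig,
    x0: float,
    v0: float,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the noiseless, unclipped PD dynamics.

    In the goal error ``e = goal - x`` the model is the damped oscillator
    ``e'' + k_d e' + k_p e = 0`` with ``e(0) = goal - x0``, ``e'(0) = -v0``.
    The under-, critically- and over-damped branches are selected by the
    sign of ``k_d^2 - 4 k_p``.

    Returns ``(position, velocity)`` evaluated at the given time points.
    """
    t = np.asarray(t, dtype=float)
    k_p, k_d = params.k_p, params.k_d
    goal = config.goal
    e0 = goal - x0
    ed0 = -v0

    disc = k_d * k_d - 4.0 * k_p
    alpha = k_d / 2.0
    # near-critical discriminants are folded into the critical branch to
    # avoid catastrophic cancellation in the 1/omega and 1/(r1-r2) terms
    if abs(disc) < 1e-12 * (k_d * k_d + 4.0 * k_p):
        a, b = e0, ed0 + alpha * e0
        decay = np.exp(-alpha * t)
        e = (a + b * t) * decay
        ed = (b - alpha * (a + b * t)) * decay
    elif disc < 0:
        omega = math.sqrt(-disc) / 2.0
        a, b = e0, (ed0 + alpha * e0) / omega
        decay = np.exp(-alpha * t)
        c, s = np.cos(omega * t), np.sin(omega * t)
        e = decay * (a * c + b * s)
        ed = decay * ((b * omega - alpha * a) * c - (a * omega + alpha * b) * s)
    else:
        root = math.sqrt(disc)
        r1, r2 = (-k_d + root) / 2.0, (-k_d - root) / 2.0
        a = (ed0 - r2 * e0) / (r1 - r2)
        b = e0 - a
        e = a * np.exp(r1 * t) + b * np.exp(r2 * t)
        ed = a * r1 * np.exp(r1 * t) + b * r2 * np.exp(r2 * t)

    return goal - e, -ed


def damping_ratio(params: PDParams | float, k_d: float | None = None) -> float:
    """Damping ratio ``k_d / (2 sqrt(k_p))``; values < 1 predict overshoot.

    Accepts either a :class:`PDParams` or raw ``(k_p, k_d)`` gains; the raw
    form admits the boundary case ``k_d = 0`` (undamped) that ``PDParams``
    rejects.
    """
    if isinstance(params, PDParams):
        k_p, k_d = params.k_p, params.k_d
    else:
        if k_d is None:
            raise TypeError("damping_ratio(k_p, k_d) requires both gains")
        k_p = float(params)
    if k_p <= 0:
        raise ValueError("damping ratio requires k_p > 0")
    return k_d / (2.0 * math.sqrt(k_p))
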