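"""Trajectory-learning agent (tML): generative kinematics plus the MeSH rule.

The agent represents a foraging trajectory with two continuous policy
parameters — a speed gain ``A`` setting trajectory amplitude and a heading
offset ``Omega`` setting its orientation.  Each trial it samples executed
values ``a[i] ~ N(A, sigma_a)`` and ``omega[i] ~ N(Omega, sigma_omega)``,
generates heading and speed time series

    Theta(t) = L(-pi, pi) + omega[i] + eps        (linear heading sweep)
    S(t)     = G(tau, sigma) * a[i] + eps         (Gaussian speed bumps)

path-integrates them into a roughly elliptical out-and-back trajectory, and
updates the policy with a mean-shift-plus-homeostasis (MeSH) rule

    A[i+1] = A[i] + alpha * (a[i] - A[i]) * upsilon[i] - beta * (a[i] - A[0])

(and identically for Omega), where ``upsilon[i]`` is an exponentially
smoothed local reward rate.  The mean shift drags the policy toward executed
values when rewards are flowing; the homeostatic term pulls the executed
behavior back toward an innate default ``A[0]``.

The module also implements the four optogenetic-perturbation variants of
the learning update, a hazard-gated model of self-initiated movement timing
(optionally gated on synchronous population events, SPEs), and a tabular
epsilon-greedy Q baseline agent for comparison.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import norm

from .envsim import (
    ArenaSpec,
    BlockSchedule,
    JoystickSpec,
    TrialOutcome,
    evaluate_ntf_trajectory,
    evaluate_stf_trajectory,
)

__all__ = [
    "PolicyState",
    "TrajectoryShape",
    "NoiseSpec",
    "MeshParams",
    "PerturbationSpec",
    "InitiationSpec",
    "SimTrial",
    "SimResult",
    "generate_heading",
    "generate_speed",
    "integrate_trajectory",
    "calibrate_shape",
    "update_reward_rate",
    "mesh_update",
    "apply_perturbation",
    "run_session",
    "sample_initiation_time",
    "sample_initiation_times",
    "run_q_baseline",
    "default_stf_shape",
    "default_ntf_shape",
    "default_stf_policy",
    "default_ntf_policy",
]

PERTURBATION_VARIANTS = (
    "none",
    "default_policy",
    "reward_not_detected",
    "learning_bias",
    "reduced_learning",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolicyState:
    """Learned trajectory parameters and their innate defaults."""

    A: float
    Omega: float
    A0: float
    Omega0: float
    sigma_a: float
    sigma_omega: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.A0 <= 0:
            raise ValueError("speed gains must be positive")
        if self.sigma_a < 0 or self.sigma_omega < 0:
            raise ValueError("sampling s.d. must be non-negative")
        if abs(self.Omega) > math.pi + 1e-12:
            raise ValueError("heading offset outside [-pi, pi]")


@dataclass(frozen=True)
class TrajectoryShape:
    """Speed-profile template: 1 (NTF) or 2 (STF) Gaussian peaks."""

    tau: tuple[float, ...]
    sigma: float
    duration: float
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not all(0.0 < t < self.duration for t in self.tau):
            raise ValueError("peak times must lie strictly inside the duration")
        if self.dt >= self.sigma:
            raise ValueError("dt must be small relative to sigma")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class NoiseSpec:
    """Additive smoothed Gaussian noise on one control channel.

    ``amplitude`` is the standard deviation of the noise *after* smoothing
    (white noise is drawn at a compensating level and box-car smoothed over
    ``smoothing_window`` seconds, which preserves zero mean).
    """

    amplitude: float = 0.0
    smoothing_window: float = 0.15

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    def sample(self, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.zeros(n)
        w = max(1, int(round(self.smoothing_window / dt)))
        white = rng.standard_normal(n) * (self.amplitude * math.sqrt(w))
        return uniform_filter1d(white, size=w, mode="nearest")

    def sample_many(
        self, m: int, n: int, dt: float, rng: np.random.Generator
    ) -> np.ndarray:
        """(m, n) independent noise traces; same statistics as `sample`."""
        if self.amplitude == 0.0:
            return np.zeros((m, n))
        w = max(1, int(round(self.smoothing_window / dt)))
        white = rng.standard_normal((m, n)) * (self.amplitude * math.sqrt(w))
        return uniform_filter1d(white, size=w, mode="nearest", axis=1)


@dataclass(frozen=True)
class MeshParams:
    """MeSH rates: forward learning ``alpha``, homeostatic ``beta``, and the
    exponential smoothing constant ``reward_smoothing`` (lambda) of the
    local reward-rate estimate upsilon."""

    alpha: float = 0.5
    beta: float = 0.03
    reward_smoothing: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.reward_smoothing <= 1.0:
            raise ValueError("reward_smoothing must lie in (0, 1]")


@dataclass(frozen=True)
class PerturbationSpec:
    """One of the four modelled inactivation variants of the MeSH update.

    variant:
        ``default_policy``      policy reverts to the default (A0, Omega0);
        ``reward_not_detected`` update recomputed as if the trial were
                                unrewarded (reward went undetected);
        ``learning_bias``       exaggerated update, increment scaled by
                                ``gain`` (10 by default);
        ``reduced_learning``    attenuated update, increment scaled by
                                ``gain`` in [0, 0.1] (default 0.05).
    """

    variant: str = "none"
    gain: float | None = None
    trial_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.variant not in PERTURBATION_VARIANTS:
            raise ValueError(f"unknown perturbation variant {self.variant!r}")
        if self.gain is None:
            default = {"learning_bias": 10.0, "reduced_learning": 0.05}
            object.__setattr__(self, "gain", default.get(self.variant, 1.0))
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.variant == "reduced_learning" and not 0.0 <= self.gain <= 0.1:
            raise ValueError("reduced_learning gain must lie in [0, 0.1]")
        object.__setattr__(self, "trial_mask", frozenset(self.trial_mask))


@dataclass(frozen=True)
class InitiationSpec:
    """Hazard-gated model of self-initiated movement timing.

    The hazard H(t) = g(t) / (1 - G(t)) is built from a Gaussian latency
    density g with mean 3 s and s.d. 0.48 s so that, ungated, sampled
    latencies reproduce g (truncated at zero).  When ``spe_gate`` is on,
    initiation additionally requires an SPE: at least one since the start
    of the trial window (``gate_mode='latched'``, default) or one within
    the last ``gate_window`` seconds (``gate_mode='sliding'`` — a transient
    eligibility trace that decays after each SPE).  Simulated laser
    inactivation thins SPEs inside ``laser_windows`` to ``laser_spe_factor``
    of their baseline probability (~75% reduction) and emits a rebound SPE
    at laser offset with probability ``rebound_prob``.
    """

    hazard_mean: float = 3.0
    hazard_sd: float = 0.48
    spe_gate: bool = False
    spe_rate: float = 0.5
    spe_interval_sampler: Callable[[np.random.Generator], float] | None = None
    laser_windows: tuple[tuple[float, float], ...] = ()
    laser_spe_factor: float = 0.25
    rebound_prob: float = 0.9
    gate_mode: str = "latched"
    gate_window: float = 0.5

    def __post_init__(self) -> None:
        if self.hazard_sd <= 0:
            raise ValueError("hazard_sd must be positive")
        if self.gate_mode not in ("latched", "sliding"):
            raise ValueError("gate_mode must be 'latched' or 'sliding'")
        if self.gate_window <= 0:
            raise ValueError("gate_window must be positive")
        if not 0.0 <= self.laser_spe_factor <= 1.0:
            raise ValueError("laser_spe_factor must lie in [0, 1]")
        if not 0.0 <= self.rebound_prob <= 1.0:
            raise ValueError("rebound_prob must lie in [0, 1]")
        object.__setattr__(
            self, "laser_windows", tuple(tuple(w) for w in self.laser_windows)
        )


@dataclass(frozen=True)
class SimTrial:
    """Per-trial record of one simulated attempt."""

    index: int
    block_target: int
    a: float
    omega: float
    max_amplitude: float
    outcome: TrialOutcome
    upsilon: float
    perturbed: bool
    initiation_latency: float | None = None
    trajectory: np.ndarray | None = None

    @property
    def rewarded(self) -> bool:
        return self.outcome.rewarded


@dataclass(frozen=True)
class SimResult:
    """Full history of one simulated session."""

    trials: tuple[SimTrial, ...]
    schedule: BlockSchedule
    policy_history: tuple[PolicyState, ...]
    config: dict
    seed: object

    def __post_init__(self) -> None:
        if len(self.policy_history) != len(self.trials) + 1:
            raise ValueError("policy_history must have one entry per trial + 1")

    def amplitudes(self) -> np.ndarray:
        return np.array([t.max_amplitude for t in self.trials])

    def rewards(self) -> np.ndarray:
        return np.array([t.rewarded for t in self.trials], dtype=bool)


# ---------------------------------------------------------------------------
# generative kinematics
# ---------------------------------------------------------------------------

def generate_heading(
    shape: TrajectoryShape,
    omega_i: float,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Heading series: linear sweep from -pi to pi plus offset and noise."""
    base = np.linspace(-math.pi, math.pi, shape.n_samples) + omega_i
    if noise is None or noise.amplitude == 0.0:
        return base
    if rng is None:
        raise ValueError("rng required when noise amplitude > 0")
    return base + noise.sample(shape.n_samples, shape.dt, rng)


@lru_cache(maxsize=32)
def _speed_template(shape: TrajectoryShape) -> np.ndarray:
    t = shape.times()
    bumps = np.zeros_like(t)
    for tau in shape.tau:
        bumps += np.exp(-0.5 * ((t - tau) / shape.sigma) ** 2)
    return bumps


def generate_speed(
    shape: TrajectoryShape,
    a_i: float,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Speed series: sum of Gaussian bumps at ``tau`` scaled by gain ``a_i``."""
    if a_i < 0:
        raise ValueError("speed gain must be non-negative")
    s = _speed_template(shape) * a_i
    if noise is None or noise.amplitude == 0.0:
        return s.copy()
    if rng is None:
        raise ValueError("rng required when noise amplitude > 0")
    return s + noise.sample(shape.n_samples, shape.dt, rng)


def integrate_trajectory(
    heading: np.ndarray,
    speed: np.ndarray,
    origin: Sequence[float] = (0.0, 0.0),
    dt: float = 0.01,
) -> np.ndarray:
    """Path-integrate heading/speed control signals into positions.

    position[k+1] = position[k] + speed[k] * (cos heading[k], sin heading[k]) * dt
    with position[0] = origin; returns an (N + 1, 2) array.
    """
    heading = np.asarray(heading, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if heading.shape != speed.shape or heading.ndim != 1:
        raise ValueError("heading and speed must be equal-length 1-D series")
    steps = (speed * dt)[:, None] * np.stack(
        [np.cos(heading), np.sin(heading)], axis=1
    )
    out = np.empty((len(speed) + 1, 2))
    out[0] = origin
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += np.asarray(origin, dtype=float)
    return out


def calibrate_shape(shape: TrajectoryShape) -> tuple[float, float]:
    """Noiseless amplitude-per-gain and excursion direction of a shape.

    Returns ``(amp_per_gain, excursion_angle)``: the maximum radial
    excursion produced by unit gain with zero heading offset, and the polar
    angle (radians, standard math convention) of that far point.  The
    noiseless excursion is exactly linear in the gain, so the map
    ``amplitude = amp_per_gain * a`` converts between gain and reach.
    """
    heading = generate_heading(shape, 0.0)
    speed = generate_speed(shape, 1.0)
    traj = integrate_trajectory(heading, speed, (0.0, 0.0), shape.dt)
    r = np.hypot(traj[:, 0], traj[:, 1])
    k = int(np.argmax(r))
    return float(r[k]), float(math.atan2(traj[k, 1], traj[k, 0]))


# ---------------------------------------------------------------------------
# defaults (STF arena units: cm; NTF joystick units: mm)
# ---------------------------------------------------------------------------

def default_stf_shape() -> TrajectoryShape:
    """Double-peaked speed profile: 4 s out-and-back loop, peaks at 1 s / 3 s."""
    return TrajectoryShape(tau=(1.0, 3.0), sigma=0.5, duration=4.0, dt=0.01)


def default_ntf_shape() -> TrajectoryShape:
    """Single-peaked forelimb movement, ~0.5 s timescale within a 1.5 s trial."""
    return TrajectoryShape(tau=(0.5,), sigma=0.15, duration=1.5, dt=0.01)


#: Default smoothed-noise levels for the two control channels (heading in
#: radians, speed in cm/s), giving a modest within-trajectory wobble on top
#: of the trial-to-trial parameter sampling.
DEFAULT_HEADING_NOISE = NoiseSpec(0.10)
DEFAULT_SPEED_NOISE = NoiseSpec(2.0)


def default_stf_policy(
    default_amplitude: float = 34.0,
    shape: TrajectoryShape | None = None,
    sigma_a_frac: float = 0.3,
    sigma_omega: float = 0.1,
) -> PolicyState:
    """Default STF policy: a trained animal's reach of ~34 cm (the near
    target), aimed along the target axis.

    The homeostatic default anchors at the near-target distance — these
    sessions model trained animals, whose baseline excursions match the
    first block's target — so adapting to the far target (52 cm) requires
    reward-driven up-scaling against the homeostatic pull.  ``Omega0`` is
    set so the noiseless excursion points along +y (toward the targets);
    ``sigma_a`` defaults to 30% of ``A0`` (trial-to-trial exploration).
    """
    shape = shape or default_stf_shape()
    amp_per_gain, angle = calibrate_shape(shape)
    a0 = default_amplitude / amp_per_gain
    omega0 = _wrap_angle(math.pi / 2.0 - angle)
    return PolicyState(
        A=a0,
        Omega=omega0,
        A0=a0,
        Omega0=omega0,
        sigma_a=sigma_a_frac * a0,
        sigma_omega=sigma_omega,
    )


def default_ntf_policy(
    default_amplitude: float = 3.0,
    shape: TrajectoryShape | None = None,
    sigma_a_frac: float = 0.25,
) -> PolicyState:
    """Default NTF policy: innate displacement ~3 mm, below the 4-6 mm band."""
    shape = shape or default_ntf_shape()
    amp_per_gain, _ = calibrate_shape(shape)
    a0 = default_amplitude / amp_per_gain
    return PolicyState(
        A=a0, Omega=0.0, A0=a0, Omega0=0.0,
        sigma_a=sigma_a_frac * a0, sigma_omega=0.0,
    )


def _wrap_angle(x: float) -> float:
    return float((x + math.pi) % (2.0 * math.pi) - math.pi)


# ---------------------------------------------------------------------------
# MeSH learning rule and perturbations
# ---------------------------------------------------------------------------

def update_reward_rate(upsilon_prev: float, rewarded: bool, lam: float) -> float:
    """Exponentially smoothed local reward rate.

    upsilon' = (1 - lam) * upsilon_prev + lam * 1{rewarded}; stays in [0, 1].
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("smoothing constant lambda must lie in (0, 1]")
    if not 0.0 <= upsilon_prev <= 1.0:
        raise ValueError("upsilon must lie in [0, 1]")
    return (1.0 - lam) * upsilon_prev + lam * (1.0 if rewarded else 0.0)


def mesh_update(
    policy: PolicyState,
    a_i: float,
    omega_i: float,
    upsilon: float,
    params: MeshParams,
) -> PolicyState:
    """One MeSH step on both policy parameters.

    A'     = A     + alpha * (a_i - A) * upsilon         - beta * (a_i - A0)
    Omega' = Omega + alpha * (omega_i - Omega) * upsilon - beta * (omega_i - Omega0)

    Heading differences are taken on the circle (wrapped to (-pi, pi]), so
    an offset sitting near +/-pi updates continuously rather than jumping
    by ~2*pi when a sampled omega_i wraps.
    """
    a_new = (
        policy.A
        + params.alpha * (a_i - policy.A) * upsilon
        - params.beta * (a_i - policy.A0)
    )
    om_new = (
        policy.Omega
        + params.alpha * _wrap_angle(omega_i - policy.Omega) * upsilon
        - params.beta * _wrap_angle(omega_i - policy.Omega0)
    )
    return replace(policy, A=max(a_new, 1e-9), Omega=_wrap_angle(om_new))


def apply_perturbation(
    before: PolicyState,
    after: PolicyState,
    spec: PerturbationSpec,
    trial_index: int,
    *,
    unrewarded_after: PolicyState | None = None,
) -> PolicyState:
    """Apply one of the inactivation variants to a base MeSH update.

    ``before`` / ``after`` bracket the unperturbed update; the MeSH
    increment is their per-parameter difference.  For the
    ``reward_not_detected`` variant the caller must supply
    ``unrewarded_after`` — the state the update would have produced had the
    reward gone undetected (the upsilon path differs, so it cannot be
    reconstructed from the increment alone).
    """
    if spec.variant == "none" or trial_index not in spec.trial_mask:
        return after
    if spec.variant == "default_policy":
        return replace(after, A=before.A0, Omega=before.Omega0)
    if spec.variant == "reward_not_detected":
        if unrewarded_after is None:
            raise ValueError(
                "reward_not_detected requires the recomputed unrewarded update"
            )
        return unrewarded_after
    if spec.variant in ("learning_bias", "reduced_learning"):
        d_a = after.A - before.A
        d_om = _wrap_angle(after.Omega - before.Omega)
        return replace(
            after,
            A=max(before.A + spec.gain * d_a, 1e-9),
            Omega=_wrap_angle(before.Omega + spec.gain * d_om),
        )
    raise ValueError(f"unknown perturbation variant {spec.variant!r}")


# ---------------------------------------------------------------------------
# session loop
# ---------------------------------------------------------------------------

def run_session(
    env: ArenaSpec | JoystickSpec,
    schedule: BlockSchedule,
    policy0: PolicyState,
    shape: TrajectoryShape,
    mesh: MeshParams,
    *,
    heading_noise: NoiseSpec = NoiseSpec(0.0),
    speed_noise: NoiseSpec = NoiseSpec(0.0),
    pert: PerturbationSpec | None = None,
    seed: int | np.random.Generator | None = None,
    task: str | None = None,
    upsilon0: float = 0.0,
    keep_trajectories: bool = True,
    initiation: InitiationSpec | None = None,
    initiation_window: float = 12.0,
) -> SimResult:
    """Simulate a full session of the trajectory-learning agent.

    Per trial: sample (a_i, omega_i) around the current policy, generate
    and path-integrate the trajectory, score it against the environment's
    reward rule, update the smoothed reward rate with the outcome, apply the
    MeSH update and (on masked trials) the perturbation variant.  Fully
    reproducible given ``seed``.  For the NTF task the heading parameter is
    frozen (amplitude-only learning) and the trajectory is the 1-D radial
    joystick displacement.
    """
    if task is None:
        task = "stf" if isinstance(env, ArenaSpec) else "ntf"
    if task not in ("stf", "ntf"):
        raise ValueError("task must be 'stf' or 'ntf'")
    n_trials = schedule.n_trials
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pert = pert or PerturbationSpec("none")
    n = shape.n_samples
    # Pre-drawn randomness (keeps the per-trial loop cheap): standard-normal
    # deviates for (a_i, omega_i) and smoothed noise traces for both channels.
    z_a = rng.standard_normal(n_trials)
    z_om = rng.standard_normal(n_trials)
    noise_h = heading_noise.sample_many(n_trials, n, shape.dt, rng)
    noise_s = speed_noise.sample_many(n_trials, n, shape.dt, rng)
    base_heading = np.linspace(-math.pi, math.pi, n)
    bumps = _speed_template(shape)
    targets = schedule.targets()
    origin = np.asarray(
        env.port_xy if isinstance(env, ArenaSpec) else (0.0, 0.0), dtype=float
    )

    policy = policy0
    upsilon = upsilon0
    trials: list[SimTrial] = []
    history: list[PolicyState] = [policy0]
    for i in range(n_trials):
        a_i = max(policy.A + policy.sigma_a * z_a[i], 0.0)
        if task == "stf":
            omega_i = _wrap_angle(policy.Omega + policy.sigma_omega * z_om[i])
            heading = base_heading + omega_i + noise_h[i]
        else:
            omega_i = 0.0
            heading = np.zeros(n)  # 1-D displacement along +x
        speed = bumps * a_i + noise_s[i]
        traj = integrate_trajectory(heading, speed, origin, shape.dt)
        rel = traj - origin
        radii = np.hypot(rel[:, 0], rel[:, 1])
        if task == "stf":
            outcome = evaluate_stf_trajectory(traj, env, int(targets[i]), shape.dt)
        else:
            outcome = evaluate_ntf_trajectory(rel, env, int(targets[i]), shape.dt)

        ups_reward = update_reward_rate(
            upsilon, outcome.rewarded, mesh.reward_smoothing
        )
        after = mesh_update(policy, a_i, omega_i, ups_reward, mesh)
        if task == "ntf":
            after = replace(after, Omega=policy.Omega)  # heading frozen
        perturbed = pert.variant != "none" and i in pert.trial_mask
        if perturbed:
            ups_unrew = update_reward_rate(upsilon, False, mesh.reward_smoothing)
            unrew_after = mesh_update(policy, a_i, omega_i, ups_unrew, mesh)
            if task == "ntf":
                unrew_after = replace(unrew_after, Omega=policy.Omega)
            new_policy = apply_perturbation(
                policy, after, pert, i, unrewarded_after=unrew_after
            )
            upsilon = ups_unrew if pert.variant == "reward_not_detected" else ups_reward
        else:
            new_policy = after
            upsilon = ups_reward

        latency = None
        if initiation is not None:
            latency, _ = sample_initiation_time(initiation, initiation_window, rng)
        trials.append(
            SimTrial(
                index=i,
                block_target=int(targets[i]),
                a=float(a_i),
                omega=float(omega_i),
                max_amplitude=float(radii.max()),
                outcome=outcome,
                upsilon=float(upsilon),
                perturbed=perturbed,
                initiation_latency=latency,
                trajectory=traj if keep_trajectories else None,
            )
        )
        history.append(new_policy)
        policy = new_policy

    config = {
        "task": task,
        "shape": {"tau": list(shape.tau), "sigma": shape.sigma,
                  "duration": shape.duration, "dt": shape.dt},
        "mesh": {"alpha": mesh.alpha, "beta": mesh.beta,
                 "reward_smoothing": mesh.reward_smoothing},
        "policy0": {"A": policy0.A, "Omega": policy0.Omega, "A0": policy0.A0,
                    "Omega0": policy0.Omega0, "sigma_a": policy0.sigma_a,
                    "sigma_omega": policy0.sigma_omega},
        "heading_noise": {"amplitude": heading_noise.amplitude,
                          "smoothing_window": heading_noise.smoothing_window},
        "speed_noise": {"amplitude": speed_noise.amplitude,
                        "smoothing_window": speed_noise.smoothing_window},
        "perturbation": {"variant": pert.variant, "gain": pert.gain,
                         "n_masked": len(pert.trial_mask)},
    }
    return SimResult(
        trials=tuple(trials),
        schedule=schedule,
        policy_history=tuple(history),
        config=config,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


# ---------------------------------------------------------------------------
# hazard-gated movement initiation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _hazard_step_probs(
    mean: float, sd: float, window: float, dt: float
) -> np.ndarray:
    """Per-step initiation probabilities H(t) * dt on the trial-window grid."""
    t = (np.arange(int(round(window / dt))) + 1) * dt
    g = norm.pdf(t, mean, sd)
    G = norm.cdf(t, mean, sd)
    H = g / np.clip(1.0 - G, 1e-300, None)
    return np.clip(H * dt, 0.0, 1.0)


def _sample_spe_times(
    spec: InitiationSpec, window: float, rng: np.random.Generator
) -> np.ndarray:
    """SPE times within [0, window]: renewal process, laser-thinned + rebound."""
    times: list[float] = []
    t = 0.0
    while True:
        if spec.spe_interval_sampler is not None:
            t += float(spec.spe_interval_sampler(rng))
        else:
            t += float(rng.exponential(1.0 / spec.spe_rate))
        if t >= window:
            break
        times.append(t)
    if spec.laser_windows:
        kept = []
        for s in times:
            in_laser = any(on <= s < off for on, off in spec.laser_windows)
            if not in_laser or rng.random() < spec.laser_spe_factor:
                kept.append(s)
        times = kept
        for on, off in spec.laser_windows:
            if off <= window and rng.random() < spec.rebound_prob:
                times.append(off)
    return np.sort(np.asarray(times))


def _gate_closed_steps(
    spe_times: np.ndarray, spec: InitiationSpec, n_steps: int, dt: float
) -> np.ndarray | None:
    """Boolean mask of steps where the SPE gate is closed (None = all open)."""
    if len(spe_times) == 0:
        return np.ones(n_steps, dtype=bool)
    if spec.gate_mode == "latched":
        closed = np.zeros(n_steps, dtype=bool)
        first_open = int(np.ceil(spe_times[0] / dt))
        closed[: min(first_open, n_steps)] = True
        return closed if first_open > 0 else None
    open_mask = np.zeros(n_steps, dtype=bool)
    for s in spe_times:  # open during [s, s + gate_window]
        lo = max(0, int(np.ceil(s / dt)) - 1)
        hi = min(n_steps, int(np.floor((s + spec.gate_window) / dt)))
        open_mask[lo:hi] = True
    return ~open_mask


def sample_initiation_time(
    spec: InitiationSpec,
    trial_window: float,
    rng: np.random.Generator,
    dt: float = 0.005,
) -> tuple[float | None, np.ndarray]:
    """Sample one movement-initiation latency and the trial's SPE times.

    Initiation occurs at the first time step where a uniform draw falls
    below the hazard probability H(t) * dt and — if ``spe_gate`` — the SPE
    gate is open (see :class:`InitiationSpec` for the latched vs sliding
    gate semantics).  Returns ``(latency_or_None, spe_times)``.
    """
    if trial_window <= 0:
        raise ValueError("trial_window must be positive")
    spe_times = _sample_spe_times(spec, trial_window, rng)
    p = _hazard_step_probs(spec.hazard_mean, spec.hazard_sd, trial_window, dt)
    hits = rng.random(len(p)) < p
    if spec.spe_gate:
        closed = _gate_closed_steps(spe_times, spec, len(p), dt)
        if closed is not None:
            hits &= ~closed
    idx = np.flatnonzero(hits)
    if len(idx) == 0:
        return None, spe_times
    return float((idx[0] + 1) * dt), spe_times


def sample_initiation_times(
    spec: InitiationSpec,
    trial_window: float,
    n: int,
    rng: np.random.Generator,
    dt: float = 0.005,
) -> np.ndarray:
    """Vectorised batch of ``n`` latencies (NaN where no initiation occurs).

    Equivalent to ``n`` calls of :func:`sample_initiation_time` but drawn in
    chunks; used for distribution-level checks and laser-delay simulations.
    """
    p = _hazard_step_probs(spec.hazard_mean, spec.hazard_sd, trial_window, dt)
    out = np.full(n, np.nan)
    gated = spec.spe_gate or spec.laser_windows
    chunk = max(1, min(n, int(4e6 // max(len(p), 1))))
    pos = 0
    while pos < n:
        m = min(chunk, n - pos)
        hits = rng.random((m, len(p))) < p
        if gated:
            for j in range(m):
                spe_times = _sample_spe_times(spec, trial_window, rng)
                if spec.spe_gate:
                    closed = _gate_closed_steps(spe_times, spec, len(p), dt)
                    if closed is not None:
                        hits[j] &= ~closed
        any_hit = hits.any(axis=1)
        first = hits.argmax(axis=1)
        vals = (first + 1) * dt
        out[pos:pos + m] = np.where(any_hit, vals, np.nan)
        pos += m
    return out


# ---------------------------------------------------------------------------
# epsilon-greedy Q baseline
# ---------------------------------------------------------------------------

def run_q_baseline(
    arena: ArenaSpec,
    epsilon: float,
    n_trajectories: int,
    seed: int | np.random.Generator | None = None,
    *,
    goal_target: int = 1,
    cell_size: float = 3.0,
    step_cap: int = 500,
) -> list[np.ndarray]:
    """Trajectories of a converged epsilon-greedy tabular agent.

    The value function is assumed converged and optimal for the *goal*
    target: V(s) = -(shortest-path distance to the goal cell) on a grid of
    ``cell_size`` cells with 8-connected moves.  At each step the agent
    takes the argmax-value neighbour with probability 1 - epsilon and a
    uniformly random neighbour otherwise; epsilon = 1 is a pure random
    walk.  Trajectories start at the port and end at the goal or at
    ``step_cap`` steps.  Returns per-trajectory (n_steps, 2) position
    arrays in cm.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    nx = int(round(arena.width / cell_size))
    ny = int(round(arena.height / cell_size))
    x_lo = -arena.width / 2.0

    def to_cell(x: float, y: float) -> tuple[int, int]:
        return (
            min(nx - 1, max(0, int((x - x_lo) / cell_size))),
            min(ny - 1, max(0, int(y / cell_size))),
        )

    def to_xy(c: tuple[int, int]) -> tuple[float, float]:
        return (x_lo + (c[0] + 0.5) * cell_size, (c[1] + 0.5) * cell_size)

    goal = to_cell(*arena.target_rects[goal_target].center)
    start = to_cell(*arena.port_xy)
    # BFS distance-to-goal over the (obstacle-free) grid, 8-connected
    dist = np.full((nx, ny), np.inf)
    dist[goal] = 0.0
    dq = deque([goal])
    moves = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    while dq:
        cx, cy = dq.popleft()
        for dx, dy in moves:
            px, py = cx + dx, cy + dy
            if 0 <= px < nx and 0 <= py < ny and not np.isfinite(dist[px, py]):
                dist[px, py] = dist[cx, cy] + 1.0
                dq.append((px, py))
    if not np.isfinite(dist[start]):
        raise ValueError("goal unreachable from start")
    value = -dist

    trajectories = []
    for _ in range(n_trajectories):
        cell = start
        path = [to_xy(cell)]
        for _ in range(step_cap):
            if cell == goal:
                break
            neighbors = [
                (cell[0] + dx, cell[1] + dy)
                for dx, dy in moves
                if 0 <= cell[0] + dx < nx and 0 <= cell[1] + dy < ny
            ]
            if rng.random() < epsilon:
                cell = neighbors[rng.integers(len(neighbors))]
            else:
                vals = np.array([value[c] for c in neighbors])
                best = np.flatnonzero(vals == vals.max())
                cell = neighbors[best[rng.integers(len(best))] if len(best) > 1
                                 else best[0]]
            path.append(to_xy(cell))
        trajectories.append(np.asarray(path))
    return trajectories
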