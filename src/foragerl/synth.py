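"""Synthetic behavioral and neural sessions with known ground truth.

Every downstream analysis in this package is validated against data from
this generator: simulated agent sessions are stitched into continuous
position traces with rest periods, reward and laser event logs; aligned
ROI activity is generated from Gaussian place fields (arena task) or
movement-phase tuning (joystick task) with heavy-tailed peak rates,
synchronous population events (SPEs) injected at a controlled rate and
timing, and dF/F derived from spikes by exponential-kernel convolution.

The generator states a world, not a fit: its defaults are the task
parameters of the modelled experiments (75 cm arena, two 80-trial blocks,
~0.5 Hz SPEs, ~15-20% participation) plus explicitly documented choices
where the experiments specify none (GCaMP6f-like 0.5 s calcium decay,
log-normal peak rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .agent import (
    DEFAULT_HEADING_NOISE,
    DEFAULT_SPEED_NOISE,
    MeshParams,
    NoiseSpec,
    PerturbationSpec,
    PolicyState,
    SimResult,
    TrajectoryShape,
    default_ntf_policy,
    default_ntf_shape,
    default_stf_policy,
    default_stf_shape,
    run_session,
)
from .behavior import PositionTrace
from .envsim import ArenaSpec, BlockSchedule, JoystickSpec
from .neural import RoiMatrix

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "synth_behavior_session",
    "synth_neural_session",
    "sequence_trials",
    "null_peth_session",
]


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of one synthetic session."""

    task: Literal["stf", "ntf"] = "stf"
    schedule: BlockSchedule | None = None
    policy: PolicyState | None = None
    mesh: MeshParams = field(default_factory=MeshParams)
    shape: TrajectoryShape | None = None
    heading_noise: NoiseSpec = DEFAULT_HEADING_NOISE
    speed_noise: NoiseSpec = DEFAULT_SPEED_NOISE
    perturbation: PerturbationSpec | None = None
    laser_fraction: float = 0.0          # catch-trial fraction when pert set
    # neural generator
    n_rois: int = 100
    field_width: float = 8.0             # cm (STF place fields)
    peak_rate_median: float = 5.0        # Hz, log-normal median
    peak_rate_sigma_log: float = 1.0     # heavy-tailed propensity
    baseline_rate: float = 0.1           # Hz
    phase_width: float = 0.2             # s (NTF movement-phase tuning)
    spe_rate: float = 0.5                # Hz within eligible windows
    spe_timing: Literal["retrospective", "prospective"] = "retrospective"
    spe_participation: float = 0.2
    n_ensembles: int = 3
    ensemble_by_covariate: bool = False  # tie ensemble identity to behavior
    frame_rate: float = 10.0
    calcium_tau: float = 0.5             # s, GCaMP6f-like decay
    dff_noise: float = 0.1
    # session stitching
    rest_mean: float = 3.0               # s of extra rest beyond the re-arm
    rest_sd: float = 0.48
    seed: int = 0

    def resolved(self) -> "SynthConfig":
        """Config with task-appropriate defaults filled in."""
        sched = self.schedule
        shape = self.shape
        policy = self.policy
        if self.task == "stf":
            sched = sched or BlockSchedule(((1, 80), (2, 80)))
            shape = shape or default_stf_shape()
            policy = policy or default_stf_policy(shape=shape)
        else:
            sched = sched or BlockSchedule(((1, 40), (2, 40)))
            shape = shape or default_ntf_shape()
            policy = policy or default_ntf_policy(shape=shape)
            if len(shape.tau) != 1:
                raise ValueError("NTF task requires a single-peaked shape")
        if self.task == "stf" and len(shape.tau) != 2:
            raise ValueError("STF task requires a double-peaked shape")
        return replace(self, schedule=sched, shape=shape, policy=policy)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    # behavior
    trial_start: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_stop: np.ndarray = field(default_factory=lambda: np.empty(0))
    a: np.ndarray = field(default_factory=lambda: np.empty(0))
    omega: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitude: np.ndarray = field(default_factory=lambda: np.empty(0))
    rewarded: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    laser: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    block: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    sim_result: SimResult | None = None
    # neural
    field_centers: np.ndarray | None = None
    pref_latency: np.ndarray | None = None
    peak_rates: np.ndarray | None = None
    spe_times: np.ndarray | None = None
    spe_frames: np.ndarray | None = None
    spe_ensemble_id: np.ndarray | None = None
    ensembles: list[np.ndarray] | None = None


# ---------------------------------------------------------------------------
# behavioral session
# ---------------------------------------------------------------------------

def synth_behavior_session(
    cfg: SynthConfig,
) -> tuple[PositionTrace, dict, GroundTruth]:
    """Generate one continuous behavioral session.

    Runs the learning agent through the task schedule and stitches the
    per-trial trajectories into a continuous position trace at
    ``cfg.frame_rate``, separated by rest periods at the port (re-arm delay
    plus a Gaussian-distributed self-initiation latency).  Returns the
    trace, an event log (reward times, laser times, per-frame block id) and
    the ground truth.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    if cfg.task == "stf":
        env = ArenaSpec()
        rearm = env.trial_rearm_delay
    else:
        env = JoystickSpec()
        rearm = env.iti
    n_trials = cfg.schedule.n_trials
    pert = cfg.perturbation
    if pert is not None and cfg.laser_fraction > 0 and not pert.trial_mask:
        mask = frozenset(
            int(i) for i in np.flatnonzero(
                rng.random(n_trials) < cfg.laser_fraction
            )
        )
        pert = replace(pert, trial_mask=mask)
    sim = run_session(
        env, cfg.schedule, cfg.policy, cfg.shape, cfg.mesh,
        heading_noise=cfg.heading_noise, speed_noise=cfg.speed_noise,
        pert=pert, seed=rng, keep_trajectories=True,
    )
    dt = cfg.shape.dt
    port = np.asarray(env.port_xy if cfg.task == "stf" else (0.0, 0.0))
    xs, ys = [], []
    reward_times: list[float] = []
    laser_times: list[float] = []
    t_starts, t_stops = [], []
    block_bounds: list[int] = []
    t_cursor = 0.0
    jitter_sd = 0.2 if cfg.task == "stf" else 0.02
    for trial in sim.trials:
        rest = rearm + max(0.5, rng.normal(cfg.rest_mean, cfg.rest_sd))
        n_rest = int(round(rest / dt))
        xs.append(port[0] + rng.normal(0, jitter_sd, n_rest))
        ys.append(port[1] + rng.normal(0, jitter_sd, n_rest))
        t_cursor += n_rest * dt
        traj = trial.trajectory
        t_starts.append(t_cursor)
        xs.append(traj[:, 0])
        ys.append(traj[:, 1])
        if trial.rewarded:
            reward_times.append(t_cursor + trial.outcome.reward_time)
        t_cursor += len(traj) * dt
        t_stops.append(t_cursor)
        if cfg.task == "ntf":
            # passive spring return of the joystick to rest
            n_ret = int(round(0.5 / dt))
            xs.append(np.linspace(traj[-1, 0], port[0], n_ret))
            ys.append(np.linspace(traj[-1, 1], port[1], n_ret))
            t_cursor += n_ret * dt
        if trial.perturbed:
            laser_times.append(t_stops[-1])  # collection-window inactivation
        block_bounds.append(trial.block_target)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x)) * dt
    # resample to the imaging frame rate
    t_f = np.arange(0.0, t[-1], 1.0 / cfg.frame_rate)
    trace = PositionTrace(
        t_f, np.interp(t_f, t, x), np.interp(t_f, t, y),
        source="body" if cfg.task == "stf" else "joystick",
        sample_rate=cfg.frame_rate,
    )
    events = {
        "reward_times": np.asarray(reward_times),
        "laser_times": np.asarray(laser_times),
        "block_of_trial": np.asarray(block_bounds),
    }
    truth = GroundTruth(
        trial_start=np.asarray(t_starts),
        trial_stop=np.asarray(t_stops),
        a=np.array([tr.a for tr in sim.trials]),
        omega=np.array([tr.omega for tr in sim.trials]),
        amplitude=sim.amplitudes(),
        rewarded=sim.rewards(),
        laser=np.array([tr.perturbed for tr in sim.trials], dtype=bool),
        block=np.asarray(block_bounds),
        sim_result=sim,
    )
    return trace, events, truth


# ---------------------------------------------------------------------------
# neural session
# ---------------------------------------------------------------------------

def _dff_from_spikes(
    spikes: np.ndarray, frame_rate: float, tau: float, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_kernel = max(1, int(round(5 * tau * frame_rate)))
    kernel = np.exp(-np.arange(n_kernel) / (tau * frame_rate))
    dff = np.apply_along_axis(
        lambda v: np.convolve(v, kernel)[: len(v)], 1, spikes.astype(float)
    )
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, dff.shape)
    return dff


def synth_neural_session(
    trace: PositionTrace,
    truth: GroundTruth,
    cfg: SynthConfig,
) -> tuple[RoiMatrix, GroundTruth]:
    """Generate ROI activity aligned to a synthetic behavioral session.

    Spike trains are inhomogeneous Poisson: in the arena task each ROI has
    a Gaussian place field (centres sampled from *visited* positions so
    every field is testable); in the joystick task each ROI is tuned to a
    preferred latency from movement onset.  Peak rates are log-normal
    (heavy-tailed activation propensity).  SPEs are injected at
    ``cfg.spe_rate`` within eligible windows — the 2 s after trajectory
    stop (retrospective, arena) or the 2 s before movement onset
    (prospective, joystick) — each recruiting ``spe_participation`` of the
    population from a small set of recurring ensembles.  dF/F is the
    exponential-kernel convolution of the spikes plus Gaussian noise.

    Returns the RoiMatrix and the ground truth extended with the neural
    fields.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed + 1)
    fr = cfg.frame_rate
    n_frames = len(trace.t)
    n_rois = cfg.n_rois
    dt = 1.0 / fr
    peak = cfg.peak_rate_median * np.exp(
        rng.normal(0.0, cfg.peak_rate_sigma_log, n_rois)
    )
    speed = trace.speed()
    moving = speed >= 1.0
    rates = np.full((n_rois, n_frames), cfg.baseline_rate)
    field_centers = None
    pref_latency = None
    if cfg.task == "stf":
        pick = rng.choice(np.flatnonzero(moving), size=n_rois, replace=True)
        field_centers = np.stack(
            [trace.x[pick], trace.y[pick]], axis=1
        ) + rng.normal(0, 1.0, (n_rois, 2))
        d2 = (
            (trace.x[None, :] - field_centers[:, 0:1]) ** 2
            + (trace.y[None, :] - field_centers[:, 1:2]) ** 2
        )
        tuning = np.exp(-d2 / (2 * cfg.field_width**2))
        rates += peak[:, None] * tuning * moving[None, :]
    else:
        move_dur = float(np.median(truth.trial_stop - truth.trial_start))
        pref_latency = rng.uniform(0.0, move_dur, n_rois)
        for t0 in truth.trial_start:
            lo = int(t0 * fr)
            hi = min(n_frames, lo + int(move_dur * fr) + 1)
            tt = trace.t[lo:hi] - t0
            bump = np.exp(
                -((tt[None, :] - pref_latency[:, None]) ** 2)
                / (2 * cfg.phase_width**2)
            )
            rates[:, lo:hi] += peak[:, None] * bump
    spikes = rng.poisson(rates * dt)

    # ---- SPE injection ------------------------------------------------
    ensembles = [
        np.sort(rng.choice(
            n_rois, size=int(round(cfg.spe_participation * n_rois)),
            replace=False,
        ))
        for _ in range(cfg.n_ensembles)
    ]
    windows: list[tuple[float, float, int]] = []  # (t0, t1, trial)
    for i, (t0, t1) in enumerate(zip(truth.trial_start, truth.trial_stop)):
        if cfg.spe_timing == "retrospective":
            lo, hi = t1, t1 + 2.0
            if i + 1 < len(truth.trial_start):
                hi = min(hi, truth.trial_start[i + 1])
        else:
            lo, hi = t0 - 2.0, t0
            if i > 0:
                lo = max(lo, truth.trial_stop[i - 1])
        if hi - lo > 2 * dt:
            windows.append((lo, hi, i))
    spe_times: list[float] = []
    spe_trial: list[int] = []
    for lo, hi, i in windows:
        n_ev = rng.poisson(cfg.spe_rate * (hi - lo))
        for _ in range(n_ev):
            spe_times.append(float(rng.uniform(lo, hi)))
            spe_trial.append(i)
    order = np.argsort(spe_times)
    spe_times_arr = np.asarray(spe_times)[order]
    spe_trial_arr = np.asarray(spe_trial, dtype=int)[order]
    if cfg.ensemble_by_covariate and len(spe_times_arr):
        # ensemble identity tracks a behavioral covariate: heading offset
        # (arena) or target block (joystick), quantile-binned
        cov = (
            truth.omega if cfg.task == "stf" else truth.block.astype(float)
        )[spe_trial_arr]
        qs = np.quantile(cov, np.linspace(0, 1, cfg.n_ensembles + 1)[1:-1])
        ens_id = np.digitize(cov, qs)
    else:
        ens_id = rng.integers(0, cfg.n_ensembles, len(spe_times_arr))
    spe_frames = np.clip(
        np.round(spe_times_arr * fr).astype(int), 0, n_frames - 1
    )
    for f, e in zip(spe_frames, ens_id):
        members = ensembles[int(e)]
        offs = rng.integers(0, 2, len(members))  # within one 200 ms window
        cols = np.clip(f + offs, 0, n_frames - 1)
        spikes[members, cols] += 1

    dff = _dff_from_spikes(spikes, fr, cfg.calcium_tau, cfg.dff_noise, rng)
    roi = RoiMatrix(
        dff=dff, spikes=spikes, frame_rate=fr, frame_times=trace.t.copy()
    )
    truth_out = replace_ground_truth(
        truth,
        field_centers=field_centers,
        pref_latency=pref_latency,
        peak_rates=peak,
        spe_times=spe_times_arr,
        spe_frames=spe_frames,
        spe_ensemble_id=np.asarray(ens_id, dtype=int),
        ensembles=ensembles,
    )
    return roi, truth_out


def replace_ground_truth(truth: GroundTruth, **kwargs) -> GroundTruth:
    out = GroundTruth(**{**truth.__dict__, **kwargs})
    return out


# ---------------------------------------------------------------------------
# named generator regimes
# ---------------------------------------------------------------------------

def spe_regime(seed: int = 0, **overrides) -> SynthConfig:
    """SPE-detection regime: injected ensemble events on sparse background.

    Place-field tuning is switched off so the raster is a sparse Poisson
    background (0.1 Hz per ROI) plus the injected 20%-participation SPEs —
    the regime in which detection recall and false-event rate are
    measured.
    """
    return SynthConfig(seed=seed, peak_rate_median=0.0, **overrides)


def decoder_regime(seed: int = 0, **overrides) -> SynthConfig:
    """Position-decoding positive-control regime.

    A large, strongly tuned population (400 ROIs, 60 Hz median peak rate,
    12 cm fields, mild rate dispersion) so that linear decodability — not
    sampling noise — is what the consensus-decoder contract tests.  Rates
    are deliberately higher than calcium-imaging event rates.
    """
    kwargs = dict(
        n_rois=400,
        peak_rate_median=60.0,
        peak_rate_sigma_log=0.5,
        field_width=12.0,
    )
    kwargs.update(overrides)
    return SynthConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# focused positive-control generators
# ---------------------------------------------------------------------------

def sequence_trials(
    n_rois: int = 50,
    n_trials: int = 20,
    n_timepoints: int = 40,
    noise_sd: float = 0.05,
    frame_rate: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Movement-locked sequential activity with known ROI latencies.

    Each ROI responds at a distinct latency within every trial window
    (a stereotyped sequence) plus Gaussian noise.  Returns (activity
    matrix, trial windows, true latency order) — the positive control for
    peri-movement sorting and reliability analyses.
    """
    rng = (
        np.random.default_rng(rng)
        if not isinstance(rng, np.random.Generator) else rng
    )
    latencies = rng.permutation(n_rois) * (n_timepoints - 1) // max(n_rois - 1, 1)
    gap = n_timepoints // 2
    stride = n_timepoints + gap
    n_frames = n_trials * stride + gap
    activity = rng.normal(0.0, noise_sd, (n_rois, n_frames))
    windows = []
    tt = np.arange(n_timepoints)
    for k in range(n_trials):
        start = gap + k * stride
        windows.append((start, start + n_timepoints))
        bump = np.exp(-0.5 * ((tt[None, :] - latencies[:, None]) / 1.5) ** 2)
        activity[:, start:start + n_timepoints] += bump
    return activity, windows, np.argsort(latencies, kind="stable")


def null_peth_session(
    n_trials: int = 30,
    movement_rate: float = 0.5,
    window: float = 12.0,
    catch_fraction: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null PETH session: identical movement statistics on catch and control.

    Movement events form a homogeneous Poisson process after every align
    event; catch labels are assigned at random, so any detected
    catch-control difference is a false positive.  Returns
    (movement_times, align_events, catch_mask).
    """
    rng = (
        np.random.default_rng(rng)
        if not isinstance(rng, np.random.Generator) else rng
    )
    spacing = window + 3.0
    align = np.arange(n_trials) * spacing
    times = []
    for ev in align:
        n = rng.poisson(movement_rate * window)
        times.extend(np.sort(rng.uniform(0, window, n)) + ev)
    catch = np.zeros(n_trials, dtype=bool)
    n_catch = max(5, int(round(catch_fraction * n_trials)))
    catch[rng.choice(n_trials, n_catch, replace=False)] = True
    return np.asarray(times), align, catch
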