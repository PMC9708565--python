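"""Grid-search fitting of agent parameters to switch-aligned behavior.

The observable being fit is the mean maximum trajectory amplitude aligned
to the target-switch trial, averaged across sessions.  The two fitted
parameters are the forward learning rate ``alpha`` and the exploration
s.d. ``sigma_a`` of the executed gain; for each grid pair a batch of
sessions is simulated, the switch-aligned amplitude curve computed, and
the pair minimising the mean squared error against the observed curve is
returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .agent import (
    DEFAULT_HEADING_NOISE,
    DEFAULT_SPEED_NOISE,
    MeshParams,
    NoiseSpec,
    PolicyState,
    TrajectoryShape,
    default_stf_policy,
    default_stf_shape,
    run_session,
)
from .envsim import ArenaSpec, BlockSchedule

__all__ = [
    "SwitchAlignedCurve",
    "FitResult",
    "switch_aligned_summary",
    "grid_search_fit",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_SIGMA_FRAC_GRID",
]

#: Default 5 x 5 search grid (25 parameter pairs): forward learning rate and
#: exploration s.d. expressed as a fraction of the default gain A0.
DEFAULT_ALPHA_GRID = (0.05, 0.1, 0.2, 0.4, 0.8)
DEFAULT_SIGMA_FRAC_GRID = (0.05, 0.1, 0.15, 0.2, 0.3)


@dataclass(frozen=True)
class SwitchAlignedCurve:
    """Per-offset mean and s.e.m. of max amplitude relative to the switch.

    ``hit_rate``, when present, is the switch-aligned mean interception
    probability over the same offsets (used by the joint fitting loss).
    """

    trial_offsets: np.ndarray
    mean_amplitude: np.ndarray
    sem: np.ndarray
    n_sessions: int
    hit_rate: np.ndarray | None = None
    hit_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (
            len(self.trial_offsets) == len(self.mean_amplitude) == len(self.sem)
        ):
            raise ValueError("curve arrays must be congruent")


@dataclass(frozen=True)
class FitResult:
    grid: tuple[tuple[float, float], ...]
    loss_surface: np.ndarray
    best_pair: tuple[float, float]
    n_sims_per_pair: int
    seed: int | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "grid": [list(p) for p in self.grid],
                    "loss_surface": self.loss_surface.tolist(),
                    "best_pair": list(self.best_pair),
                    "n_sims_per_pair": self.n_sims_per_pair,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    def loss_matrix_csv(self, path, alphas, sigma_fracs) -> None:
        """Loss surface as a CSV matrix (rows alphas, columns sigma fracs)."""
        mat = self.loss_surface.reshape(len(alphas), len(sigma_fracs))
        header = "alpha\\sigma," + ",".join(str(s) for s in sigma_fracs)
        lines = [header] + [
            f"{a}," + ",".join(f"{v:.6g}" for v in row)
            for a, row in zip(alphas, mat)
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def switch_aligned_summary(
    session_amplitudes: Sequence[np.ndarray],
    switch_indices: Sequence[int],
    window: tuple[int, int] = (10, 40),
) -> SwitchAlignedCurve:
    """Align per-trial amplitudes to the target switch and average.

    Parameters
    ----------
    session_amplitudes : one array of per-trial max amplitudes per session.
    switch_indices : trial index at which the second block starts, per session.
    window : (pre, post) counts of trials around the switch; offset 0 is the
        first trial of the new block.  Sessions too short for the window are
        truncated with a warning (missing offsets averaged over fewer
        sessions).
    """
    pre, post = window
    offsets = np.arange(-pre, post)
    acc = np.full((len(session_amplitudes), len(offsets)), np.nan)
    for s, (amps, sw) in enumerate(zip(session_amplitudes, switch_indices)):
        amps = np.asarray(amps, dtype=float)
        idx = sw + offsets
        valid = (idx >= 0) & (idx < len(amps))
        if not valid.all():
            warnings.warn(
                f"session {s}: window exceeds session length; truncating",
                stacklevel=2,
            )
        acc[s, valid] = amps[idx[valid]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(acc, axis=0)
        n_per = np.sum(np.isfinite(acc), axis=0)
        sd = np.nanstd(acc, axis=0, ddof=1)
    sem = np.where(n_per > 1, sd / np.sqrt(np.maximum(n_per, 1)), 0.0)
    return SwitchAlignedCurve(
        trial_offsets=offsets,
        mean_amplitude=mean,
        sem=sem,
        n_sessions=len(session_amplitudes),
    )


def simulate_switch_curve(
    alpha: float,
    sigma_a: float,
    n_sims: int,
    rng: np.random.Generator,
    *,
    arena: ArenaSpec | None = None,
    schedule: BlockSchedule | None = None,
    policy0: PolicyState | None = None,
    shape: TrajectoryShape | None = None,
    mesh: MeshParams | None = None,
    heading_noise: NoiseSpec = DEFAULT_HEADING_NOISE,
    speed_noise: NoiseSpec = DEFAULT_SPEED_NOISE,
    window: tuple[int, int] = (10, 40),
) -> SwitchAlignedCurve:
    """Switch-aligned amplitude curve from ``n_sims`` simulated sessions."""
    arena = arena or ArenaSpec()
    schedule = schedule or BlockSchedule()
    shape = shape or default_stf_shape()
    policy0 = policy0 or default_stf_policy(shape=shape)
    mesh = mesh or MeshParams()
    mesh = dc_replace(mesh, alpha=alpha)
    policy0 = dc_replace(policy0, sigma_a=sigma_a)
    sw = schedule.switch_indices[0]
    amps, sws, rews = [], [], []
    for _ in range(n_sims):
        res = run_session(
            arena, schedule, policy0, shape, mesh,
            heading_noise=heading_noise, speed_noise=speed_noise,
            seed=rng, keep_trajectories=False,
        )
        amps.append(res.amplitudes())
        rews.append(res.rewards().astype(float))
        sws.append(sw)
    curve = switch_aligned_summary(amps, sws, window)
    hit_curve = switch_aligned_summary(rews, sws, window)
    return SwitchAlignedCurve(
        trial_offsets=curve.trial_offsets,
        mean_amplitude=curve.mean_amplitude,
        sem=curve.sem,
        n_sessions=curve.n_sessions,
        hit_rate=hit_curve.mean_amplitude,
        hit_sem=hit_curve.sem,
    )


def grid_search_fit(
    observed: SwitchAlignedCurve,
    *,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    sigma_fracs: Sequence[float] = DEFAULT_SIGMA_FRAC_GRID,
    n_sims: int = 10,
    seed: int | None = None,
    sem_weighted: bool = False,
    loss: str = "joint",
    window: tuple[int, int] = (10, 40),
    **session_kwargs,
) -> FitResult:
    """Fit (alpha, sigma_a) by grid search against an observed switch curve.

    For each of the (by default 25) parameter pairs, ``n_sims`` sessions are
    simulated with common random numbers (every pair re-seeds the same
    stream, so loss differences reflect parameters, not simulation noise)
    and compared to the observed curve.  ``loss='amplitude'`` is the mean
    squared error of the switch-aligned mean-amplitude curve (optionally
    s.e.m.-weighted); ``loss='joint'`` (default) adds the switch-aligned
    interception-probability curve, each term normalised by the observed
    curve's variance — amplitude and hit-rate together break the
    (alpha, sigma_a) trade-off that the amplitude curve alone leaves
    under-determined.  Ties break toward smaller alpha.  ``sigma_a`` grid
    values are fractions of the default gain ``A0``.
    """
    if len(alphas) == 0 or len(sigma_fracs) == 0:
        raise ValueError("grid must be non-empty")
    if not np.all(np.isfinite(observed.mean_amplitude)):
        raise ValueError("observed curve must be finite")
    if loss not in ("amplitude", "joint"):
        raise ValueError("loss must be 'amplitude' or 'joint'")
    if loss == "joint" and observed.hit_rate is None:
        raise ValueError("joint loss requires an observed hit-rate curve")
    policy_ref = session_kwargs.get("policy0") or default_stf_policy(
        shape=session_kwargs.get("shape") or default_stf_shape()
    )
    obs = observed.mean_amplitude
    if sem_weighted:
        w = 1.0 / np.clip(observed.sem, np.median(observed.sem[observed.sem > 0])
                          if np.any(observed.sem > 0) else 1.0, None) ** 2
    else:
        w = np.ones_like(obs)
    amp_scale = max(float(np.var(obs)), 1e-12)
    hit_scale = (
        max(float(np.var(observed.hit_rate)), 1e-12)
        if loss == "joint" else 1.0
    )
    grid: list[tuple[float, float]] = []
    losses: list[float] = []
    for alpha in alphas:  # iteration order guarantees smaller-alpha tie-break
        for frac in sigma_fracs:
            sigma_a = frac * policy_ref.A0
            rng = np.random.default_rng(seed)  # common random numbers
            curve = simulate_switch_curve(
                alpha, sigma_a, n_sims, rng, window=window, **session_kwargs
            )
            resid = curve.mean_amplitude - obs
            val = float(np.sum(w * resid**2) / np.sum(w)) / (
                amp_scale if loss == "joint" else 1.0
            )
            if loss == "joint":
                hit_resid = curve.hit_rate - observed.hit_rate
                val += float(np.mean(hit_resid**2)) / hit_scale
            losses.append(val)
            grid.append((alpha, frac))
    losses_arr = np.asarray(losses)
    if not np.any(np.isfinite(losses_arr)):
        raise RuntimeError("all grid losses non-finite")
    best = int(np.nanargmin(losses_arr))  # first minimum -> smallest alpha
    return FitResult(
        grid=tuple(grid),
        loss_surface=losses_arr,
        best_pair=grid[best],
        n_sims_per_pair=n_sims,
        seed=seed,
    )
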