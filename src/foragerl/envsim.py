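"""Simulated foraging-task environments.

Two task geometries are modelled:

* **STF** (spatial target foraging): a freely moving animal in a square
  arena runs from a reward port into an unmarked rectangular target area,
  which triggers reward delivery, and then returns to a collection area
  around the port to consume the reward.
* **NTF** (non-navigational target foraging): a head-fixed animal displaces
  a spring-loaded joystick into a hidden radial target band; brief
  occupancy of the band arms a delayed reward.

Coordinates place the reward port at the origin with the y axis pointing
into the arena.  STF positions are in centimetres, NTF displacements in
millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np
import yaml

__all__ = [
    "Rect",
    "ArenaSpec",
    "JoystickSpec",
    "BlockSchedule",
    "TrialOutcome",
    "evaluate_stf_trajectory",
    "evaluate_ntf_trajectory",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with closed boundaries."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate rectangle")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised closed-boundary point-in-rectangle test."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    @classmethod
    def from_center(cls, cx: float, cy: float, width: float, height: float) -> "Rect":
        return cls(cx - width / 2, cy - height / 2, cx + width / 2, cy + height / 2)


@dataclass(frozen=True)
class ArenaSpec:
    """STF arena geometry and trial timing.

    Defaults follow the task design: a 75 cm x 75 cm box, a 20 cm x 14 cm
    collection area around the water spout (the port, at the origin, on one
    wall), and two unmarked 18 cm x 14 cm target areas whose centres lie
    ~34 cm (target 1) and ~52 cm (target 2) from the reward area.  A new
    trial arms 2 s after the animal enters the collection area.
    """

    width: float = 75.0
    height: float = 75.0
    port_xy: tuple[float, float] = (0.0, 0.0)
    collection_rect: Rect = field(
        default_factory=lambda: Rect.from_center(0.0, 7.0, 20.0, 14.0)
    )
    target_rects: dict[int, Rect] = field(
        default_factory=lambda: {
            1: Rect.from_center(0.0, 34.0, 18.0, 14.0),
            2: Rect.from_center(0.0, 52.0, 18.0, 14.0),
        }
    )
    trial_rearm_delay: float = 2.0

    def __post_init__(self) -> None:
        x_lo, x_hi = -self.width / 2.0, self.width / 2.0
        for tid, rect in self.target_rects.items():
            if not (x_lo <= rect.x_min and rect.x_max <= x_hi and
                    0.0 <= rect.y_min and rect.y_max <= self.height):
                raise ValueError(f"target rect {tid} outside arena")
            c = self.collection_rect
            overlap = not (rect.x_max < c.x_min or rect.x_min > c.x_max or
                           rect.y_max < c.y_min or rect.y_min > c.y_max)
            if overlap:
                raise ValueError(f"target rect {tid} overlaps collection area")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["collection_rect"] = asdict(self.collection_rect)
        d["target_rects"] = {k: asdict(v) for k, v in self.target_rects.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        d = dict(d)
        d["port_xy"] = tuple(d["port_xy"])
        d["collection_rect"] = Rect(**d["collection_rect"])
        d["target_rects"] = {int(k): Rect(**v) for k, v in d["target_rects"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ArenaSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def geometry_json(self) -> str:
        """Arena geometry as JSON, for plotting tools."""
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class JoystickSpec:
    """NTF joystick task parameters.

    Reward is delivered 1 s after the qualifying band occupancy (~100 ms),
    followed by a 3.3 s inter-trial interval; 40 trials per block.  Target
    band radii (mm) are configurable; defaults put block 1 at 4-6 mm and
    block 2 at 8-10 mm from the joystick rest position.
    """

    target_bands: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (4.0, 6.0), 2: (8.0, 10.0)}
    )
    occupancy_required: float = 0.1
    reward_delay: float = 1.0
    iti: float = 3.3
    trials_per_block: int = 40

    def __post_init__(self) -> None:
        for bid, (lo, hi) in self.target_bands.items():
            if not (0.0 < lo < hi):
                raise ValueError(f"invalid target band {bid}: [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_bands"] = {k: list(v) for k, v in self.target_bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "JoystickSpec":
        d = dict(d)
        d["target_bands"] = {int(k): tuple(v) for k, v in d["target_bands"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "JoystickSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered blocks of (target_id, n_trials); default two blocks of 80."""

    entries: tuple[tuple[int, int], ...] = ((1, 80), (2, 80))

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("empty schedule")
        for tid, n in self.entries:
            if n <= 0:
                raise ValueError("block lengths must be positive")

    @property
    def n_trials(self) -> int:
        return sum(n for _, n in self.entries)

    @property
    def switch_indices(self) -> tuple[int, ...]:
        """Trial indices at which a new block starts (first block excluded)."""
        cum = np.cumsum([n for _, n in self.entries])
        return tuple(int(i) for i in cum[:-1])

    def target_for_trial(self, i: int) -> int:
        if not 0 <= i < self.n_trials:
            raise IndexError(f"trial {i} outside schedule")
        for tid, n in self.entries:
            if i < n:
                return tid
            i -= n
        raise AssertionError("unreachable")

    def targets(self) -> np.ndarray:
        """Per-trial active target id, length n_trials."""
        return np.concatenate([np.full(n, tid, dtype=int) for tid, n in self.entries])


@dataclass(frozen=True)
class TrialOutcome:
    rewarded: bool
    intercept_time: float | None = None
    reward_time: float | None = None
    returned_home: bool = False

    def __post_init__(self) -> None:
        if self.rewarded and self.intercept_time is None:
            raise ValueError("rewarded outcome requires an intercept time")


def evaluate_stf_trajectory(
    traj: np.ndarray,
    arena: ArenaSpec,
    active_target: int,
    dt: float = 0.01,
) -> TrialOutcome:
    """Score one STF trajectory against the arena reward rule.

    Reward triggers on the first sample inside the active target rectangle
    (interception at any point along the trajectory).  ``returned_home`` is
    true if a later sample enters the collection area.

    Parameters
    ----------
    traj : (N, 2) array of positions in cm, sampled at uniform ``dt``.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[0] == 0 or traj.shape[1] != 2:
        raise ValueError("trajectory must be a non-empty (N, 2) array")
    rect = arena.target_rects[active_target]  # KeyError for unknown target id
    inside = rect.contains(traj[:, 0], traj[:, 1])
    if not inside.any():
        home = bool(
            arena.collection_rect.contains(traj[:, 0], traj[:, 1]).any()
        )
        return TrialOutcome(rewarded=False, returned_home=home)
    k = int(np.argmax(inside))
    later = arena.collection_rect.contains(traj[k:, 0], traj[k:, 1])
    return TrialOutcome(
        rewarded=True,
        intercept_time=k * dt,
        reward_time=k * dt,
        returned_home=bool(later.any()),
    )


def evaluate_ntf_trajectory(
    traj: np.ndarray,
    spec: JoystickSpec,
    block: int,
    dt: float = 0.01,
) -> TrialOutcome:
    """Score one NTF joystick trace against the radial-band reward rule.

    The radial displacement must stay inside the block's target band
    ``[d_lo, d_hi]`` contiguously for at least ``occupancy_required``
    seconds; the reward is delivered ``reward_delay`` (1 s) after the
    qualifying occupancy is reached.

    Parameters
    ----------
    traj : (N, 2) array of joystick displacement in mm, or (N,) radial
        distances directly.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise ValueError("trajectory must be non-empty")
    if spec.occupancy_required < dt:
        raise ValueError(
            f"occupancy_required={spec.occupancy_required} shorter than dt={dt}"
        )
    r = np.hypot(traj[:, 0], traj[:, 1]) if traj.ndim == 2 else traj
    d_lo, d_hi = spec.target_bands[block]
    in_band = (r >= d_lo) & (r <= d_hi)
    need = int(np.ceil(spec.occupancy_required / dt))
    # first index at which `need` consecutive in-band samples have accrued
    run = 0
    for k, ok in enumerate(in_band):
        run = run + 1 if ok else 0
        if run >= need:
            t_qualify = k * dt
            return TrialOutcome(
                rewarded=True,
                intercept_time=t_qualify,
                reward_time=t_qualify + spec.reward_delay,
            )
    return TrialOutcome(rewarded=False)
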