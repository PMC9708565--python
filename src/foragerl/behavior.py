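"""Behavioral analysis: trace cleaning, attempt segmentation, learning deltas.

The pipeline mirrors standard foraging-kinematics practice: raw position
traces are despiked and Savitzky-Golay smoothed; foraging attempts are
segmented as supra-threshold radial excursions (>= 10 cm for >= 1 s in the
arena task); scalar statistics (max amplitude over the first ~500 ms,
initial heading, path length) are computed per attempt; and trial-to-trial
changes in those statistics are conditioned on the preceding trial's type
(unrewarded / rewarded / rewarded + laser inactivation) to quantify
reward-dependent updating.  A bootstrap peri-event time histogram (PETH)
compares movement rates on inactivation catch trials against controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import kruskal, mannwhitneyu

__all__ = [
    "PositionTrace",
    "Attempt",
    "DeltaTable",
    "PethResult",
    "preprocess_trace",
    "extract_attempts",
    "detect_movements",
    "performance",
    "conditional_deltas",
    "peth_bootstrap",
]

CONDITIONS = ("unrewarded", "rewarded", "rewarded_laser")


@dataclass
class PositionTrace:
    """Uniformly sampled 2-D position trace (cm for arena, mm for joystick)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source: str = "body"
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must be equal length")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError("time must be strictly increasing")
            if self.sample_rate is None:
                self.sample_rate = 1.0 / float(np.median(dts))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def speed(self) -> np.ndarray:
        """Pointwise speed, Savitzky-Golay smoothed (3rd order, 11 pts)."""
        v = np.hypot(np.diff(self.x, prepend=self.x[0]),
                     np.diff(self.y, prepend=self.y[0])) * self.sample_rate
        if len(v) >= 11:
            v = savgol_filter(v, 11, 3)
        return v


@dataclass
class Attempt:
    """One segmented foraging attempt / movement event."""

    start_idx: int
    stop_idx: int
    max_amplitude: float
    initial_heading: float
    return_heading: float
    path_length: float
    rewarded: bool
    laser: bool = False
    t_start: float = 0.0
    t_stop: float = 0.0


@dataclass
class DeltaTable:
    """Session-wise mean trial-to-trial deltas per prior-trial condition."""

    amplitude_means: dict[str, np.ndarray]
    heading_means: dict[str, np.ndarray]
    counts: dict[str, int]
    statistic: float
    pvalue: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    heading_statistic: float = np.nan
    heading_pvalue: float = np.nan

    def condition_mean(self, cond: str) -> float:
        return float(np.nanmean(self.amplitude_means[cond]))


@dataclass
class PethResult:
    time_bins: np.ndarray
    mean_control: np.ndarray
    ci_control: np.ndarray
    mean_catch: np.ndarray
    ci_catch: np.ndarray
    significant_spans: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# preprocessing and segmentation
# ---------------------------------------------------------------------------

def preprocess_trace(
    raw: PositionTrace, jump_threshold: float = 10.0
) -> PositionTrace:
    """Remove single-sample tracking jumps and Savitzky-Golay smooth.

    A sample is flagged when the position jumps away from and back toward
    its neighbours by more than ``jump_threshold`` within one frame;
    flagged samples are linearly interpolated over, then x and y are
    smoothed with a 3rd-order, 11-point Savitzky-Golay filter (which
    reproduces cubic trends exactly).  More than 20% flagged samples raises
    a quality error.
    """
    if len(raw.t) < 11:
        raise ValueError("need at least 11 samples to preprocess")
    x, y = raw.x.copy(), raw.y.copy()
    d = np.hypot(np.diff(x), np.diff(y))
    out_jump = np.concatenate([d > jump_threshold, [False]])   # i -> i+1 jump
    back_jump = np.concatenate([[False], d > jump_threshold])  # i-1 -> i jump
    flagged = back_jump & out_jump  # spike: jumps in and back out
    if flagged.mean() > 0.20:
        raise ValueError(
            f"{flagged.mean():.0%} of samples flagged as tracking errors"
        )
    if flagged.any():
        good = ~flagged
        x[flagged] = np.interp(raw.t[flagged], raw.t[good], x[good])
        y[flagged] = np.interp(raw.t[flagged], raw.t[good], y[good])
    x = savgol_filter(x, 11, 3)
    y = savgol_filter(y, 11, 3)
    return PositionTrace(raw.t.copy(), x, y, raw.source, raw.sample_rate)


def _attempt_stats(
    trace: PositionTrace, start: int, stop: int, amp_window: float
) -> tuple[float, float, float, float]:
    """(max_amplitude over first window, initial heading, return heading,
    path length) for a segment [start, stop]."""
    r = trace.radius()
    k_win = max(1, int(round(amp_window * trace.sample_rate)))
    amp = float(r[start: min(start + k_win + 1, stop + 1)].max())
    j = min(start + k_win, stop)
    dx, dy = trace.x[j] - trace.x[start], trace.y[j] - trace.y[start]
    initial = float(np.arctan2(dx, dy))  # angle from the +y axis
    j2 = max(stop - k_win, start)
    dx2, dy2 = trace.x[stop] - trace.x[j2], trace.y[stop] - trace.y[j2]
    ret = float(np.arctan2(dx2, dy2))
    seg = np.hypot(np.diff(trace.x[start:stop + 1]),
                   np.diff(trace.y[start:stop + 1]))
    return amp, initial, ret, float(seg.sum())


def extract_attempts(
    trace: PositionTrace,
    reward_times: np.ndarray | None = None,
    laser_times: np.ndarray | None = None,
    amp_threshold: float = 10.0,
    min_duration: float = 1.0,
    amp_window: float = 0.5,
    laser_extension: float = 2.0,
) -> list[Attempt]:
    """Segment foraging attempts as supra-threshold radial excursions.

    Maximal contiguous excursions whose radial distance from the port
    reaches ``amp_threshold`` and whose span is at least ``min_duration``
    become attempts; boundaries extend outward with hysteresis to where the
    radius falls below 10% of the threshold.  ``max_amplitude`` is taken
    over the first ``amp_window`` (~500 ms) of the attempt.  An attempt is
    rewarded iff a reward event falls within [start, stop]; the laser flag
    additionally looks ``laser_extension`` seconds past the stop (the
    collection-area inactivation window).
    """
    r = trace.radius()
    supra = r >= amp_threshold
    low = r < 0.1 * amp_threshold
    n = len(r)
    attempts: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1]:
            j += 1
        start = i
        while start > 0 and not low[start - 1]:
            start -= 1
        stop = j
        while stop + 1 < n and not low[stop + 1]:
            stop += 1
        if attempts and start <= attempts[-1][1]:
            attempts[-1] = (attempts[-1][0], max(stop, attempts[-1][1]))
        else:
            attempts.append((start, stop))
        i = max(stop, j) + 1
    out: list[Attempt] = []
    reward_times = np.asarray(reward_times if reward_times is not None else [])
    laser_times = np.asarray(laser_times if laser_times is not None else [])
    for start, stop in attempts:
        if (trace.t[stop] - trace.t[start]) < min_duration:
            continue
        amp, ih, rh, pl = _attempt_stats(trace, start, stop, amp_window)
        t0, t1 = trace.t[start], trace.t[stop]
        rewarded = bool(np.any((reward_times >= t0) & (reward_times <= t1)))
        laser = bool(
            np.any((laser_times >= t0) & (laser_times <= t1 + laser_extension))
        )
        out.append(
            Attempt(start, stop, amp, ih, rh, pl, rewarded, laser, t0, t1)
        )
    return out


def detect_movements(
    trace: PositionTrace,
    speed_threshold: float = 2.0,
    min_duration: float = 1.0,
    min_separation: float = 1.0,
) -> list[tuple[int, int]]:
    """Speed-threshold movement detection (joystick / NTF convention).

    Returns (start, stop) index pairs of movements at least
    ``min_duration`` long; supra-threshold runs separated by less than
    ``min_separation`` are merged (movements must be well-isolated).
    """
    v = trace.speed()
    above = v >= speed_threshold
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    merged: list[tuple[int, int]] = []
    gap = min_separation
    for start, stop in runs:
        if merged and (trace.t[start] - trace.t[merged[-1][1]]) < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return [
        (s, e) for s, e in merged
        if trace.t[e] - trace.t[s] >= min_duration
    ]


def performance(attempts: list[Attempt]) -> float:
    """P(correct | attempt): fraction of attempts that triggered reward."""
    if len(attempts) == 0:
        raise ValueError("performance undefined with zero attempts")
    return float(np.mean([a.rewarded for a in attempts]))


# ---------------------------------------------------------------------------
# prior-trial-conditioned learning deltas
# ---------------------------------------------------------------------------

def _kruskal_safe(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis that treats all-identical data as H=0, p=1."""
    if len(groups) < 2:
        return np.nan, np.nan
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = kruskal(*groups)
    return float(stat), float(p)


def _condition_of(prev: Attempt) -> str:
    if prev.rewarded and prev.laser:
        return "rewarded_laser"
    if prev.rewarded:
        return "rewarded"
    return "unrewarded"


def conditional_deltas(sessions: list[list[Attempt]]) -> DeltaTable:
    """Trial-to-trial deltas conditioned on the prior trial's type.

    For each attempt i (i >= 1), Delta = statistic(i) - statistic(i-1) for
    max amplitude and initial heading, assigned to the condition of attempt
    i-1 (unrewarded / rewarded / rewarded + laser).  Session-wise condition
    means are compared across conditions with an omnibus Kruskal-Wallis
    test; pairwise Mann-Whitney tests are Holm-corrected for the repeated
    comparisons.
    """
    amp_means: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    head_means: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    counts = {c: 0 for c in CONDITIONS}
    for attempts in sessions:
        buckets_a: dict[str, list[float]] = {c: [] for c in CONDITIONS}
        buckets_h: dict[str, list[float]] = {c: [] for c in CONDITIONS}
        for prev, cur in zip(attempts[:-1], attempts[1:]):
            cond = _condition_of(prev)
            buckets_a[cond].append(cur.max_amplitude - prev.max_amplitude)
            dh = cur.initial_heading - prev.initial_heading
            buckets_h[cond].append((dh + np.pi) % (2 * np.pi) - np.pi)
            counts[cond] += 1
        for c in CONDITIONS:
            amp_means[c].append(
                float(np.mean(buckets_a[c])) if buckets_a[c] else np.nan
            )
            head_means[c].append(
                float(np.mean(buckets_h[c])) if buckets_h[c] else np.nan
            )
    amp_arr = {c: np.asarray(v) for c, v in amp_means.items()}
    head_arr = {c: np.asarray(v) for c, v in head_means.items()}
    groups = {
        c: a[np.isfinite(a)] for c, a in amp_arr.items() if np.isfinite(a).any()
    }
    if len(groups) < len(CONDITIONS):
        missing = set(CONDITIONS) - set(groups)
        warnings.warn(
            f"conditions {sorted(missing)} empty in all sessions; "
            "test degrades to fewer groups",
            stacklevel=2,
        )
    stat, p = _kruskal_safe(list(groups.values()))
    hgroups = [
        a[np.isfinite(a)] for a in head_arr.values() if np.isfinite(a).any()
    ]
    hstat, hp = _kruskal_safe(hgroups)
    # pairwise Mann-Whitney with Holm correction over the three comparisons
    pairs = [(a, b) for k, a in enumerate(CONDITIONS) for b in CONDITIONS[k + 1:]]
    raw = {}
    for a, b in pairs:
        if a in groups and b in groups and len(groups[a]) and len(groups[b]):
            raw[(a, b)] = mannwhitneyu(
                groups[a], groups[b], alternative="two-sided"
            ).pvalue
    order = sorted(raw, key=raw.get)
    pairwise = {}
    m = len(order)
    running_max = 0.0
    for rank, key in enumerate(order):
        adj = min(1.0, (m - rank) * raw[key])
        running_max = max(running_max, adj)
        pairwise[key] = running_max
    return DeltaTable(
        amplitude_means=amp_arr,
        heading_means=head_arr,
        counts=counts,
        statistic=float(stat),
        pvalue=float(p),
        pairwise_p=pairwise,
        heading_statistic=float(hstat),
        heading_pvalue=float(hp),
    )


# ---------------------------------------------------------------------------
# PETH bootstrap for inactivation catch trials
# ---------------------------------------------------------------------------

def peth_bootstrap(
    movement_times: np.ndarray,
    align_events: np.ndarray,
    catch_mask: np.ndarray,
    window: float = 12.0,
    n_boot: int = 1000,
    bin_width: float = 0.1,
    rng: np.random.Generator | None = None,
    min_span: float = 0.2,
) -> PethResult:
    """Bootstrap PETH comparison between catch (inactivation) and control trials.

    Movement events are binned relative to each trial's align event within
    ``window`` seconds.  Each bootstrap iteration resamples (with
    replacement) k catch and k control trials — k being the number of catch
    trials — and computes their mean movement-rate PETHs; 2.5-97.5%
    percentile confidence intervals come from ``n_boot`` iterations.
    Significant spans are maximal runs of at least ``min_span`` seconds
    where the two CIs do not overlap.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = rng or np.random.default_rng()
    movement_times = np.asarray(movement_times, dtype=float)
    align_events = np.asarray(align_events, dtype=float)
    catch_mask = np.asarray(catch_mask, dtype=bool)
    if len(align_events) != len(catch_mask):
        raise ValueError("align_events and catch_mask must be congruent")
    k = int(catch_mask.sum())
    if k < 5:
        raise ValueError("need at least 5 catch trials")
    edges = np.arange(0.0, window + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    counts = np.stack([
        np.histogram(movement_times - ev, bins=edges)[0] for ev in align_events
    ]).astype(float) / bin_width  # trials x bins, in events/s
    catch_counts = counts[catch_mask]
    ctrl_counts = counts[~catch_mask]
    idx_catch = rng.integers(0, len(catch_counts), size=(n_boot, k))
    idx_ctrl = rng.integers(0, len(ctrl_counts), size=(n_boot, k))
    boot_catch = catch_counts[idx_catch].mean(axis=1)  # n_boot x bins
    boot_ctrl = ctrl_counts[idx_ctrl].mean(axis=1)
    ci_catch = np.percentile(boot_catch, [2.5, 97.5], axis=0)
    ci_ctrl = np.percentile(boot_ctrl, [2.5, 97.5], axis=0)
    disjoint = (ci_catch[1] < ci_ctrl[0]) | (ci_ctrl[1] < ci_catch[0])
    spans: list[tuple[float, float]] = []
    i = 0
    nb = len(centers)
    while i < nb:
        if not disjoint[i]:
            i += 1
            continue
        j = i
        while j + 1 < nb and disjoint[j + 1]:
            j += 1
        if (j - i + 1) * bin_width >= min_span:
            spans.append((float(edges[i]), float(edges[j + 1])))
        i = j + 1
    return PethResult(
        time_bins=centers,
        mean_control=boot_ctrl.mean(axis=0),
        ci_control=ci_ctrl,
        mean_catch=boot_catch.mean(axis=0),
        ci_catch=ci_catch,
        significant_spans=spans,
    )
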