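"""Population-imaging analysis: SPEs, place maps, decoding, ROI matching.

Operates on ROI x frame matrices of dF/F and deconvolved spike events from
one-photon calcium imaging of dorsal CA1, time-aligned to behavior.  The
analyses implemented:

* detection of synchronous population events (SPEs) — near-simultaneous
  activation of a large fraction (~15%) of the imaged population within
  ~200 ms, the imaging correlate of sharp-wave-ripple reactivation;
* k-means clustering of SPE participation vectors with silhouette model
  selection, and per-event loadings on the leading principal component of
  SPE-triggered activity windows (PC of the SPE ensemble space);
* occupancy-normalised, Gaussian-smoothed place-field rate maps;
* trial-to-trial response reliability and peri-movement sorting of ROIs;
* a consensus linear position decoder (mean of a family of pseudoinverse
  decoders trained on random trial subsets);
* cross-day ROI identity matching by spatial-footprint correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter1d
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "RoiMatrix",
    "SpeEvent",
    "RateMap",
    "DecoderModel",
    "detect_spes",
    "cluster_spes",
    "spe_pc_loadings",
    "correlate_loading_with_covariate",
    "compute_rate_map",
    "compute_rate_maps",
    "response_reliability",
    "pmth_sort",
    "train_consensus_decoder",
    "decode_and_score",
    "match_rois_across_days",
]


@dataclass
class RoiMatrix:
    """ROI x frame dF/F and inferred-spike matrices aligned to behavior."""

    dff: np.ndarray
    spikes: np.ndarray
    frame_rate: float
    frame_times: np.ndarray
    roi_footprints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.spikes = np.asarray(self.spikes)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.dff.shape != self.spikes.shape:
            raise ValueError("dff and spikes must have congruent shapes")
        if self.dff.shape[1] != len(self.frame_times):
            raise ValueError("frame_times length must match frame count")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class SpeEvent:
    """One detected synchronous population event."""

    onset_frame: int
    window: tuple[int, int]
    active_rois: frozenset[int]
    fraction_active: float
    pc_loading: float | None = None
    cluster_label: int | None = None

    @property
    def participation_vector(self) -> None:
        raise AttributeError("use event_matrix(events, n_rois)")


def event_matrix(events: list[SpeEvent], n_rois: int) -> np.ndarray:
    """Binary (n_events x n_rois) participation matrix."""
    mat = np.zeros((len(events), n_rois))
    for i, ev in enumerate(events):
        mat[i, list(ev.active_rois)] = 1.0
    return mat


@dataclass
class RateMap:
    """Occupancy-normalised, smoothed, max-normalised place-field map."""

    rate: np.ndarray              # ny x nx, NaN where masked
    occupancy_s: np.ndarray
    event_count: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    def peak_xy(self) -> tuple[float, float]:
        """Bin-centre coordinates of the peak rate."""
        if not np.any(np.isfinite(self.rate)):
            raise ValueError("rate map is empty")
        iy, ix = np.unravel_index(np.nanargmax(self.rate), self.rate.shape)
        cx = (self.x_edges[ix] + self.x_edges[ix + 1]) / 2
        cy = (self.y_edges[iy] + self.y_edges[iy + 1]) / 2
        return float(cx), float(cy)


@dataclass
class DecoderModel:
    """Consensus linear decoder: mean of per-fold pseudoinverse solutions."""

    weights: np.ndarray           # n_units x n_outputs
    n_folds: int
    trials_per_fold: int
    fold_weights: np.ndarray | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# SPE detection and ensemble structure
# ---------------------------------------------------------------------------

def detect_spes(
    spikes: np.ndarray,
    frame_rate: float,
    window: float = 0.2,
    fraction: float = 0.15,
    immobility_mask: np.ndarray | None = None,
) -> list[SpeEvent]:
    """Detect synchronous population events in a deconvolved spike raster.

    A sliding window of ``window`` seconds counts the distinct ROIs with at
    least one inferred spike; wherever that count reaches ``fraction`` of
    the imaged population, an event is declared.  Overlapping detections
    are merged, keeping local maxima of the active fraction separated by at
    least one window.  ``immobility_mask`` (per-frame boolean) optionally
    restricts detection to immobility.
    """
    spikes = np.asarray(spikes)
    if spikes.ndim != 2 or spikes.shape[0] < 20:
        raise ValueError("need a (n_rois >= 20) x n_frames raster")
    wf = int(round(window * frame_rate))
    if wf < 1:
        raise ValueError("window shorter than one frame")
    n_rois, n_frames = spikes.shape
    active = spikes > 0
    # windowed "any spike" per ROI: maximum filter with the window anchored
    # so that frame f covers [f, f + wf)
    origin = -(wf // 2) if wf > 1 else 0
    win_any = maximum_filter1d(
        active.astype(np.uint8), size=wf, axis=1, mode="constant", origin=origin
    )
    frac = win_any.sum(axis=0) / n_rois
    eligible = frac >= fraction
    if immobility_mask is not None:
        eligible &= np.asarray(immobility_mask, dtype=bool)
    events: list[SpeEvent] = []
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return events
    # split into runs, take local max of fraction per run, merge near peaks
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, run_breaks + 1)
    peaks: list[int] = []
    for run in runs:
        peak = int(run[np.argmax(frac[run])])
        if peaks and peak - peaks[-1] < wf:
            if frac[peak] > frac[peaks[-1]]:
                peaks[-1] = peak
        else:
            peaks.append(peak)
    for p in peaks:
        lo = max(0, p)
        hi = min(n_frames, p + wf)
        rois = frozenset(np.flatnonzero(active[:, lo:hi].any(axis=1)).tolist())
        events.append(
            SpeEvent(
                onset_frame=p,
                window=(lo, hi),
                active_rois=rois,
                fraction_active=float(frac[p]),
            )
        )
    return events


def cluster_spes(
    events: list[SpeEvent],
    n_rois: int,
    k_range: range = range(2, 9),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """Cluster SPE participation vectors; pick k by the silhouette method.

    k-means (20 restarts) on binary participation vectors for each k in
    ``k_range``; returns (labels at k*, k*, per-k mean silhouette scores).
    """
    k_max = max(k_range)
    if len(events) < k_max + 1:
        raise ValueError(
            f"need at least {k_max + 1} events to scan k up to {k_max}"
        )
    mat = event_matrix(events, n_rois)
    if np.allclose(mat, mat[0]):
        raise ValueError("all participation vectors identical; nothing to cluster")
    seed = (
        rng if isinstance(rng, (int, np.integer)) or rng is None
        else int(rng.integers(2**31))
    )
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed)
        with warnings.catch_warnings():
            # duplicate participation vectors legitimately collapse clusters
            warnings.simplefilter("ignore")
            labels = km.fit_predict(mat)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(mat, labels))
        labelings[k] = labels
    if not scores:
        raise ValueError("clustering degenerate at every k")
    k_star = max(scores, key=scores.get)
    labels = labelings[k_star]
    for ev, lab in zip(events, labels):
        ev.cluster_label = int(lab)
    return labels, k_star, scores


def spe_pc_loadings(
    dff: np.ndarray,
    events: list[SpeEvent],
    frame_rate: float,
    half_window: float = 0.25,
) -> np.ndarray:
    """Per-event loadings on the leading PC of SPE-triggered activity.

    Windows of +/- ``half_window`` seconds of dF/F around each event onset
    are concatenated; the leading principal component over ROIs is computed
    from that matrix; each event's loading is the mean projection of its
    window frames onto that component.  Sign convention: the
    largest-magnitude ROI weight is made positive, so loadings are
    reproducible across runs.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events")
    dff = np.asarray(dff, dtype=float)
    n_rois, n_frames = dff.shape
    hw = max(1, int(round(half_window * frame_rate)))
    slices = []
    bounds = []
    for ev in events:
        lo = ev.onset_frame - hw
        hi = ev.onset_frame + hw + 1
        if lo < 0 or hi > n_frames:
            warnings.warn("event window truncated at recording edge",
                          stacklevel=2)
            lo, hi = max(0, lo), min(n_frames, hi)
        slices.append(dff[:, lo:hi])
        bounds.append((lo, hi))
    concat = np.concatenate(slices, axis=1)           # n_rois x total_frames
    centered = concat - concat.mean(axis=1, keepdims=True)
    # leading left singular vector = PC weight vector over ROIs
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    w = u[:, 0]
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    mu = concat.mean(axis=1)
    loadings = np.empty(len(events))
    for i, sl in enumerate(slices):
        loadings[i] = float(w @ (sl.mean(axis=1) - mu))
    for ev, ld in zip(events, loadings):
        ev.pc_loading = float(ld)
    return loadings


def correlate_loading_with_covariate(
    loadings: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between SPE loadings and a behavioral covariate."""
    loadings = np.asarray(loadings, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if len(loadings) != len(covariate) or len(loadings) < 5:
        raise ValueError("need equal-length inputs with at least 5 events")
    if np.std(loadings) == 0 or np.std(covariate) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(loadings, covariate)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# place-field rate maps
# ---------------------------------------------------------------------------

def compute_rate_maps(
    spikes: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    frame_rate: float,
    *,
    arena_extent: tuple[float, float, float, float] = (-37.5, 37.5, 0.0, 75.0),
    bin_size: float = 4.0,
    speed_min: float = 1.0,
    min_visits: int = 5,
    smooth_sigma: float = 4.0,
) -> list[RateMap]:
    """Occupancy-normalised place maps for every ROI of a raster.

    Movement periods (speed >= ``speed_min`` cm/s) are selected; the arena
    is binned into ``bin_size`` cm bins; bins entered fewer than
    ``min_visits`` times are masked ("foraging bins" only).  Transient
    counts per bin are divided by occupancy seconds, Gaussian-smoothed
    (sigma = ``smooth_sigma`` cm) and max-normalised per ROI.
    """
    spikes = np.atleast_2d(np.asarray(spikes))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spikes.shape[1] != len(x) or len(x) != len(y):
        raise ValueError("spikes and positions must be frame-aligned")
    dt = 1.0 / frame_rate
    speed = np.hypot(np.diff(x, prepend=x[0]), np.diff(y, prepend=y[0])) / dt
    moving = speed >= speed_min
    if not moving.any():
        raise ValueError("no movement periods at the given speed threshold")
    x_lo, x_hi, y_lo, y_hi = arena_extent
    x_edges = np.arange(x_lo, x_hi + bin_size / 2, bin_size)
    y_edges = np.arange(y_lo, y_hi + bin_size / 2, bin_size)
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, len(y_edges) - 2)
    flat = iy * (len(x_edges) - 1) + ix
    shape2d = (len(y_edges) - 1, len(x_edges) - 1)
    nbins = shape2d[0] * shape2d[1]
    occ = np.bincount(flat[moving], minlength=nbins).astype(float) * dt
    # visits: entries into a bin during movement (bin index changes)
    mflat = flat[moving]
    entries = np.concatenate([[True], np.diff(mflat) != 0])
    visits = np.bincount(mflat[entries], minlength=nbins)
    valid = (visits >= min_visits) & (occ > 0)
    sigma_bins = smooth_sigma / bin_size
    maps: list[RateMap] = []
    valid2d = valid.reshape(shape2d)
    occ2d = occ.reshape(shape2d)
    smooth_mask = gaussian_filter(valid2d.astype(float), sigma_bins)
    for r in range(spikes.shape[0]):
        transients = (spikes[r] > 0) & moving
        cnt = np.bincount(flat[transients], minlength=nbins).astype(float)
        cnt2d = cnt.reshape(shape2d)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(valid2d, cnt2d / occ2d, 0.0)
        sm = gaussian_filter(rate * valid2d, sigma_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate_sm = np.where(smooth_mask > 1e-12, sm / smooth_mask, np.nan)
        rate_sm[~valid2d] = np.nan
        peak = np.nanmax(rate_sm) if np.any(np.isfinite(rate_sm)) else np.nan
        if np.isfinite(peak) and peak > 0:
            rate_sm = rate_sm / peak
        maps.append(
            RateMap(
                rate=rate_sm,
                occupancy_s=occ2d,
                event_count=cnt2d,
                x_edges=x_edges,
                y_edges=y_edges,
            )
        )
    return maps


def compute_rate_map(spikes_1d: np.ndarray, x, y, frame_rate, **kwargs) -> RateMap:
    """Place map for a single ROI; see :func:`compute_rate_maps`."""
    return compute_rate_maps(spikes_1d, x, y, frame_rate, **kwargs)[0]


# ---------------------------------------------------------------------------
# reliability and peri-movement sorting
# ---------------------------------------------------------------------------

def _trial_tensor(
    activity: np.ndarray, trial_windows: list[tuple[int, int]]
) -> np.ndarray:
    """(n_trials, n_rois, T) tensor of equal-length trial windows."""
    lengths = {stop - start for start, stop in trial_windows}
    if len(lengths) != 1:
        raise ValueError("trial windows must have equal length")
    return np.stack([activity[:, s:e] for s, e in trial_windows])


def response_reliability(
    activity: np.ndarray,
    trial_windows: list[tuple[int, int]],
    frame_rate: float,
    half_window: float = 0.25,
) -> np.ndarray:
    """Mean pairwise trial-to-trial correlation of population activity.

    At each within-trial timepoint, population vectors (averaged over a
    sliding +/- ``half_window`` s window) are correlated between every pair
    of trials; the mean pairwise Pearson correlation is the reliability at
    that timepoint.  Bounded [-1, 1]; NaN where activity is constant.
    """
    if len(trial_windows) < 5:
        raise ValueError("need at least 5 trials")
    tens = _trial_tensor(np.asarray(activity, dtype=float), trial_windows)
    n_trials, n_rois, T = tens.shape
    hw = max(1, int(round(half_window * frame_rate)))
    kernel = np.ones(2 * hw + 1) / (2 * hw + 1)
    sm = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), 2, tens
    )
    out = np.full(T, np.nan)
    for t in range(T):
        vecs = sm[:, :, t]
        sd = vecs.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        z = (vecs[ok] - vecs[ok].mean(axis=1, keepdims=True)) / (
            sd[ok][:, None] * np.sqrt(n_rois)
        )
        corr = z @ z.T
        iu = np.triu_indices(ok.sum(), k=1)
        out[t] = float(corr[iu].mean())
    return out


def pmth_sort(
    activity: np.ndarray,
    trial_windows: list[tuple[int, int]],
    mode: str = "crossval",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Sort ROIs by peri-movement response latency.

    ``crossval``: a random half of trials determines each ROI's time of
    peak mean response; that index array sorts the held-out half, whose
    sorted mean image is returned alongside the order.  ``hierarchical``:
    ROIs are first split around the median of session-average activity,
    then each group is sorted by latency to peak (ties fall back to a pure
    latency sort when all means are equal).
    """
    activity = np.asarray(activity, dtype=float)
    n_rois = activity.shape[0]
    if n_rois == 1:
        return np.array([0]), None
    tens = _trial_tensor(activity, trial_windows)
    if mode == "crossval":
        if len(trial_windows) < 4:
            raise ValueError("cross-validated sort needs at least 4 trials")
        rng = rng or np.random.default_rng()
        perm = rng.permutation(len(trial_windows))
        half = len(perm) // 2
        train, test = perm[:half], perm[half:]
        latency = tens[train].mean(axis=0).argmax(axis=1)
        order = np.argsort(latency, kind="stable")
        held_out = tens[test].mean(axis=0)[order]
        return order, held_out
    if mode == "hierarchical":
        mean_act = activity.mean(axis=1)
        latency = tens.mean(axis=0).argmax(axis=1)
        if np.allclose(mean_act, mean_act[0]):
            return np.argsort(latency, kind="stable"), None
        median = np.median(mean_act)
        high = np.flatnonzero(mean_act >= median)
        low = np.flatnonzero(mean_act < median)
        order = np.concatenate([
            high[np.argsort(latency[high], kind="stable")],
            low[np.argsort(latency[low], kind="stable")],
        ])
        return order, None
    raise ValueError("mode must be 'crossval' or 'hierarchical'")


# ---------------------------------------------------------------------------
# consensus decoder
# ---------------------------------------------------------------------------

def build_position_dataset(
    spikes: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    windows: list[tuple[int, int]],
    bin_frames: int = 5,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Trial-structured (F, K) dataset for position decoding.

    For each (start, stop) frame window, spike counts are summed in
    ``bin_frames``-frame bins (rows) and paired with the bin-mean (x, y)
    position.  Returns per-trial lists suitable for
    :func:`train_consensus_decoder`.
    """
    spikes = np.asarray(spikes)
    F: list[np.ndarray] = []
    K: list[np.ndarray] = []
    for lo, hi in windows:
        rows, pos = [], []
        for b in range((hi - lo) // bin_frames):
            s = lo + b * bin_frames
            e = s + bin_frames
            rows.append(spikes[:, s:e].sum(axis=1))
            pos.append([np.mean(x[s:e]), np.mean(y[s:e])])
        if rows:
            F.append(np.asarray(rows, dtype=float))
            K.append(np.asarray(pos, dtype=float))
    return F, K

def train_consensus_decoder(
    F: list[np.ndarray],
    K: list[np.ndarray],
    n_folds: int = 50,
    trials_per_fold: int = 75,
    rng: np.random.Generator | int | None = None,
) -> DecoderModel:
    """Consensus linear decoder from pseudoinverse fits on trial subsets.

    Each fold draws ``trials_per_fold`` randomly permuted trials,
    concatenates their population-activity rows (time bins x units) and
    position targets, and solves ``W = pinv(F) K`` (minimum-norm
    Moore-Penrose solution, defined even for rank-deficient folds).  The
    consensus decoder is the element-wise mean of the fold weights.
    """
    if len(F) != len(K) or len(F) == 0:
        raise ValueError("need matched, non-empty trial lists")
    if len(F) < trials_per_fold:
        raise ValueError(
            f"need at least trials_per_fold={trials_per_fold} trials"
        )
    rng = (
        np.random.default_rng(rng)
        if not isinstance(rng, np.random.Generator) else rng
    )
    fold_ws = []
    for _ in range(n_folds):
        pick = rng.permutation(len(F))[:trials_per_fold]
        X = np.concatenate([F[i] for i in pick], axis=0)
        Y = np.concatenate([K[i] for i in pick], axis=0)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("rank-deficient fold; minimum-norm solution used",
                          stacklevel=2)
        fold_ws.append(np.linalg.pinv(X) @ Y)
    fold_ws = np.stack(fold_ws)
    return DecoderModel(
        weights=fold_ws.mean(axis=0),
        n_folds=n_folds,
        trials_per_fold=trials_per_fold,
        fold_weights=fold_ws,
    )


def decode_and_score(
    model: DecoderModel,
    F_test: np.ndarray,
    K_test: np.ndarray,
    shuffle: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coefficient of determination R^2 per decoded output channel.

    Predicts ``K_hat = F_test @ W`` and scores each channel as
    ``1 - SS_res / SS_tot``.  ``shuffle=True`` permutes the weight rows
    (unit identities) before predicting — the permuted-decoder control.
    """
    F_test = np.asarray(F_test, dtype=float)
    K_test = np.asarray(K_test, dtype=float)
    W = model.weights
    if shuffle:
        rng = rng or np.random.default_rng()
        W = W[rng.permutation(W.shape[0])]
    pred = F_test @ W
    ss_tot = ((K_test - K_test.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("R^2 undefined for zero-variance target channel")
    ss_res = ((K_test - pred) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# cross-day ROI matching
# ---------------------------------------------------------------------------

def match_rois_across_days(
    footprints_day_a: np.ndarray,
    footprints_day_b: np.ndarray,
    r_threshold: float = 0.8,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one ROI matching by spatial-profile correlation.

    Both footprint stacks must be registered to a common pixel grid
    (registration itself is upstream).  Pairs with Pearson correlation
    above ``r_threshold`` are assigned in descending-r order, one-to-one.
    Returns (index_day_a, index_day_b, r) triples.
    """
    A = np.asarray(footprints_day_a, dtype=float).reshape(
        len(footprints_day_a), -1
    )
    B = np.asarray(footprints_day_b, dtype=float).reshape(
        len(footprints_day_b), -1
    )
    ok_a = A.std(axis=1) > 0
    ok_b = B.std(axis=1) > 0
    if not ok_a.all() or not ok_b.all():
        warnings.warn("empty/constant footprints skipped", stacklevel=2)
    Az = np.zeros_like(A)
    Bz = np.zeros_like(B)
    Az[ok_a] = (A[ok_a] - A[ok_a].mean(axis=1, keepdims=True)) / (
        A[ok_a].std(axis=1, keepdims=True) * np.sqrt(A.shape[1])
    )
    Bz[ok_b] = (B[ok_b] - B[ok_b].mean(axis=1, keepdims=True)) / (
        B[ok_b].std(axis=1, keepdims=True) * np.sqrt(B.shape[1])
    )
    corr = Az @ Bz.T
    pairs = [
        (float(corr[i, j]), i, j)
        for i in range(corr.shape[0])
        for j in range(corr.shape[1])
        if corr[i, j] > r_threshold
    ]
    pairs.sort(reverse=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for r, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        matches.append((i, j, r))
        used_a.add(i)
        used_b.add(j)
    return matches
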