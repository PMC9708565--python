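"""SPE detection and structure, place maps, sorting, decoding, ROI matching."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from foragerl import neural, synth


def make_raster(n_rois=100, n_frames=600, events=(), rng=None, bg_rate=0.0,
                frame_rate=10.0):
    """Raster with optional injected synchronous events.

    ``events`` is a list of (frame, roi_indices)."""
    spikes = np.zeros((n_rois, n_frames), dtype=int)
    if bg_rate > 0:
        spikes += rng.poisson(bg_rate / frame_rate, spikes.shape)
    for frame, rois in events:
        spikes[list(rois), frame] += 1
    return spikes


class TestDetectSpes:
    def test_silent_raster_yields_no_events(self):
        assert neural.detect_spes(make_raster(), 10.0) == []

    def test_single_injected_burst_detected_once(self, rng):
        spikes = make_raster(events=[(300, range(30))], rng=rng, bg_rate=0.01)
        events = neural.detect_spes(spikes, 10.0)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.onset_frame - 300) <= 2
        assert ev.fraction_active >= 0.30
        assert set(range(30)) <= set(ev.active_rois)

    def test_subthreshold_fraction_ignored(self):
        spikes = make_raster(events=[(300, range(14))])
        assert neural.detect_spes(spikes, 10.0, fraction=0.15) == []

    def test_immobility_mask_restricts_detection(self):
        spikes = make_raster(events=[(100, range(30)), (400, range(30))])
        mask = np.ones(600, bool)
        mask[:200] = False
        events = neural.detect_spes(spikes, 10.0, immobility_mask=mask)
        assert len(events) == 1
        assert abs(events[0].onset_frame - 400) <= 1

    def test_window_shorter_than_frame_rejected(self):
        with pytest.raises(ValueError):
            neural.detect_spes(make_raster(), 10.0, window=0.01)

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            neural.detect_spes(np.zeros((5, 100)), 10.0)


class TestClusterSpes:
    @staticmethod
    def _events(ensembles, n_events, rng, n_rois=100):
        events = []
        for k in range(n_events):
            rois = ensembles[k % len(ensembles)]
            events.append(neural.SpeEvent(
                onset_frame=10 * k, window=(10 * k, 10 * k + 2),
                active_rois=frozenset(int(r) for r in rois),
                fraction_active=len(rois) / n_rois,
            ))
        return events

    def test_two_disjoint_ensembles_recovered(self, rng):
        events = self._events([range(0, 20), range(50, 70)], 24, rng)
        labels, k_star, scores = neural.cluster_spes(events, 100, rng=0)
        assert k_star == 2
        assert scores[2] > 0.8
        assert len(np.unique(labels[::2])) == 1

    def test_three_ensembles_recovered_reliably(self, rng):
        ens = [range(0, 20), range(40, 60), range(75, 95)]
        hits = 0
        for seed in range(10):
            events = self._events(ens, 27, rng)
            _, k_star, _ = neural.cluster_spes(events, 100, rng=seed)
            hits += k_star == 3
        assert hits >= 9

    def test_identical_vectors_signalled(self, rng):
        events = self._events([range(0, 20)], 12, rng)
        with pytest.raises(ValueError, match="identical"):
            neural.cluster_spes(events, 100, rng=0)

    def test_too_few_events_signalled(self, rng):
        events = self._events([range(0, 20), range(30, 50)], 4, rng)
        with pytest.raises(ValueError, match="events"):
            neural.cluster_spes(events, 100, rng=0)


class TestSpeLoadings:
    @staticmethod
    def _dff_with_ensembles(rng, n_rois=60, n_frames=800):
        """dF/F with alternating orthogonal ensemble activations."""
        dff = rng.normal(0, 0.05, (n_rois, n_frames))
        events = []
        for k in range(16):
            f = 40 + 45 * k
            rois = range(0, 20) if k % 2 == 0 else range(30, 50)
            dff[list(rois), f - 2:f + 3] += 1.0
            events.append(neural.SpeEvent(
                onset_frame=f, window=(f - 1, f + 2),
                active_rois=frozenset(rois),
                fraction_active=len(list(rois)) / n_rois,
            ))
        return dff, events

    def test_alternating_ensembles_give_bimodal_signed_loadings(self, rng):
        dff, events = self._dff_with_ensembles(rng)
        loads = neural.spe_pc_loadings(dff, events, 10.0)
        even, odd = loads[::2], loads[1::2]
        assert np.sign(even.mean()) != np.sign(odd.mean())
        assert min(abs(even.mean()), abs(odd.mean())) > 3 * max(even.std(),
                                                                odd.std()) / 4

    def test_loading_invariant_to_event_order_up_to_sign(self, rng):
        dff, events = self._dff_with_ensembles(rng)
        l1 = neural.spe_pc_loadings(dff, events, 10.0)
        perm = np.random.default_rng(1).permutation(len(events))
        l2 = neural.spe_pc_loadings(dff, [events[i] for i in perm], 10.0)
        agreement = np.corrcoef(l1[perm], l2)[0, 1]
        assert abs(agreement) > 0.999

    def test_needs_three_events(self, rng):
        dff, events = self._dff_with_ensembles(rng)
        with pytest.raises(ValueError):
            neural.spe_pc_loadings(dff, events[:2], 10.0)


class TestCorrelation:
    def test_identity_and_negation(self, rng):
        loads = rng.normal(size=50)
        r, _ = neural.correlate_loading_with_covariate(loads, loads)
        assert r == pytest.approx(1.0)
        r, _ = neural.correlate_loading_with_covariate(loads, -loads)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            r, p = neural.correlate_loading_with_covariate(
                g.normal(size=1000), g.normal(size=1000)
            )
            hits += abs(r) < 0.1
        assert hits >= 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            neural.correlate_loading_with_covariate(np.ones(10), np.arange(10.0))


class TestRateMaps:
    @staticmethod
    def _grid_walk(n_steps, rng, extent=60.0):
        """Dense random-walk coverage of the arena interior."""
        pos = rng.uniform(5, extent, (n_steps, 2)) * 0 + np.stack([
            np.clip(np.cumsum(rng.normal(0, 2.0, n_steps)) % extent, 0, extent),
            np.clip(np.cumsum(rng.normal(0, 2.0, n_steps)) % extent, 0, extent),
        ], axis=1)
        return pos[:, 0] - 30.0, pos[:, 1]

    def test_uniform_firing_normalises_to_one(self, rng):
        x, y = self._grid_walk(6000, rng)
        spikes = rng.poisson(0.5, len(x))
        m = neural.compute_rate_map(spikes, x, y, 10.0)
        vals = m.rate[np.isfinite(m.rate)]
        assert vals.max() == pytest.approx(1.0)
        assert np.median(vals) > 0.3  # roughly flat after smoothing

    def test_gaussian_field_center_recovered(self, rng):
        x, y = self._grid_walk(8000, rng)
        center = (5.0, 30.0)
        rate = 8.0 * np.exp(-((x - center[0])**2 + (y - center[1])**2) / (2 * 36))
        spikes = rng.poisson(rate / 10.0)
        m = neural.compute_rate_map(spikes, x, y, 10.0)
        px, py = m.peak_xy()
        assert abs(px - center[0]) <= 4.0 and abs(py - center[1]) <= 4.0

    def test_rarely_visited_bins_masked(self, rng):
        # dwell only in one corner; distant bins must be masked
        x = np.full(2000, -20.0) + rng.normal(0, 1.5, 2000)
        y = np.full(2000, 20.0) + rng.normal(0, 1.5, 2000)
        spikes = rng.poisson(0.3, 2000)
        m = neural.compute_rate_map(spikes, x, y, 10.0)
        assert np.isnan(m.rate[-1, -1])

    def test_no_movement_signalled(self):
        with pytest.raises(ValueError, match="movement"):
            neural.compute_rate_map(np.zeros(100), np.zeros(100),
                                    np.zeros(100), 10.0)


class TestReliabilityAndSorting:
    def test_identical_trials_fully_reliable(self):
        act, wins, _ = synth.sequence_trials(noise_sd=0.0, rng=0)
        rel = neural.response_reliability(act, wins, 10.0)
        assert np.nanmin(rel) > 0.999

    def test_independent_noise_unreliable(self, rng):
        act = rng.normal(size=(40, 2000))
        wins = [(50 * k, 50 * k + 30) for k in range(20)]
        rel = neural.response_reliability(act, wins, 10.0)
        assert abs(np.nanmean(rel)) < 0.1

    def test_sequence_reliability_exceeds_iti(self):
        """Movement-locked sequences are reliable; the inter-trial gap is not."""
        act, wins, _ = synth.sequence_trials(noise_sd=0.05, rng=1)
        rel_move = neural.response_reliability(act, wins, 10.0)
        gap_wins = [(e, e + 15) for _, e in wins[:-1]]
        rel_gap = neural.response_reliability(act, gap_wins, 10.0)
        assert np.nanmean(rel_move) > np.nanmean(rel_gap) + 0.3

    def test_crossval_sort_recovers_latency_order(self):
        act, wins, true_order = synth.sequence_trials(noise_sd=0.05, rng=2)
        order, held = neural.pmth_sort(act, wins, "crossval",
                                       np.random.default_rng(3))
        rho = spearmanr(np.argsort(order), np.argsort(true_order)).statistic
        assert rho > 0.9
        assert held.shape[0] == act.shape[0]

    def test_single_roi_identity_order(self):
        act, wins, _ = synth.sequence_trials(n_rois=1, rng=0)
        order, _ = neural.pmth_sort(act, wins, "crossval",
                                    np.random.default_rng(0))
        assert list(order) == [0]

    def test_hierarchical_tie_falls_back_to_latency_sort(self):
        act, wins, true_order = synth.sequence_trials(noise_sd=0.0, rng=4)
        # equalise session-mean activity across ROIs
        act = act - act.mean(axis=1, keepdims=True)
        order, _ = neural.pmth_sort(act, wins, "hierarchical")
        rho = spearmanr(np.argsort(order), np.argsort(true_order)).statistic
        assert rho > 0.99


class TestDecoder:
    @staticmethod
    def _linear_dataset(rng, n_trials=100, t=12, units=30):
        W_true = rng.normal(size=(units, 2))
        F = [rng.normal(size=(t, units)) for _ in range(n_trials)]
        K = [f @ W_true for f in F]
        return F, K, W_true

    def test_single_fold_equals_direct_pseudoinverse(self, rng):
        F, K, _ = self._linear_dataset(rng)
        model = neural.train_consensus_decoder(F, K, n_folds=1,
                                               trials_per_fold=len(F), rng=0)
        X = np.concatenate(F)
        Y = np.concatenate(K)
        np.testing.assert_allclose(model.weights, np.linalg.pinv(X) @ Y,
                                   atol=1e-9)

    def test_exact_linear_recovery(self, rng):
        F, K, _ = self._linear_dataset(rng)
        model = neural.train_consensus_decoder(F, K, n_folds=5,
                                               trials_per_fold=60, rng=0)
        r2 = neural.decode_and_score(model, np.concatenate(F),
                                     np.concatenate(K))
        np.testing.assert_allclose(r2, 1.0, atol=1e-6)

    def test_weight_permutation_destroys_performance(self, rng):
        F, K, _ = self._linear_dataset(rng)
        model = neural.train_consensus_decoder(F, K, n_folds=5,
                                               trials_per_fold=60, rng=0)
        r2 = neural.decode_and_score(model, np.concatenate(F),
                                     np.concatenate(K), shuffle=True,
                                     rng=np.random.default_rng(1))
        assert np.all(r2 < 0.05)

    def test_predicting_the_mean_scores_zero(self):
        model = neural.DecoderModel(weights=np.zeros((5, 1)), n_folds=1,
                                    trials_per_fold=1)
        F = np.ones((50, 5))
        K = np.random.default_rng(0).normal(1.0, 1.0, (50, 1))
        K -= K.mean() - 0.0  # target centred at zero = constant prediction
        r2 = neural.decode_and_score(model, F, K)
        assert r2[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_target_rejected(self, rng):
        model = neural.DecoderModel(weights=np.zeros((5, 1)), n_folds=1,
                                    trials_per_fold=1)
        with pytest.raises(ValueError):
            neural.decode_and_score(model, rng.normal(size=(10, 5)),
                                    np.ones((10, 1)))

    def test_too_few_trials_rejected(self, rng):
        F, K, _ = self._linear_dataset(rng, n_trials=10)
        with pytest.raises(ValueError):
            neural.train_consensus_decoder(F, K, trials_per_fold=75)


class TestRoiMatching:
    @staticmethod
    def _footprints(rng, n=30, size=40):
        fp = np.zeros((n, size, size))
        for k in range(n):
            cx, cy = rng.integers(5, size - 5, 2)
            yy, xx = np.mgrid[:size, :size]
            fp[k] = np.exp(-((xx - cx)**2 + (yy - cy)**2) / 8.0)
        return fp

    def test_identical_sets_fully_matched(self, rng):
        fp = self._footprints(rng)
        matches = neural.match_rois_across_days(fp, fp)
        assert len(matches) == len(fp)
        assert all(i == j and r > 0.999 for i, j, r in matches)

    def test_disjoint_sets_unmatched(self, rng):
        a = np.zeros((5, 20, 20))
        b = np.zeros((5, 20, 20))
        a[:, :5, :5] = 1.0
        b[:, 12:17, 12:17] = 1.0
        a += rng.normal(0, 0.01, a.shape)
        b += rng.normal(0, 0.01, b.shape)
        assert neural.match_rois_across_days(a, b) == []

    def test_one_pixel_jitter_mostly_matched(self, rng):
        fp = self._footprints(rng)
        jittered = np.roll(fp, 1, axis=2)
        matches = neural.match_rois_across_days(fp, jittered)
        correct = sum(i == j for i, j, _ in matches)
        assert correct >= 0.9 * len(fp)

    def test_empty_footprint_skipped_with_warning(self, rng):
        fp = self._footprints(rng, n=5)
        fp[2] = 0.0
        with pytest.warns(UserWarning, match="footprint"):
            matches = neural.match_rois_across_days(fp, fp)
        assert all(i != 2 and j != 2 for i, j, _ in matches)
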