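"""Population-imaging pipeline on a synthetic session with ground truth.

Generates an arena session with aligned ROI activity (Gaussian place
fields plus injected synchronous population events), then runs SPE
detection, ensemble clustering, place-map recovery and consensus position
decoding, comparing each result with the generator's ground truth.
"""

import numpy as np

from foragerl import envsim, neural, synth

# --- SPEs on a sparse background ---------------------------------------
cfg = synth.spe_regime(seed=3, schedule=envsim.BlockSchedule(((1, 30), (2, 30))))
trace, events, truth = synth.synth_behavior_session(cfg)
roi, truth = synth.synth_neural_session(trace, truth, cfg)
spes = neural.detect_spes(roi.spikes, roi.frame_rate)
det = np.array([e.onset_frame for e in spes]) / roi.frame_rate
recall = np.mean([np.any(np.abs(det - t) <= 0.3) for t in truth.spe_times])
print(f"SPEs: {len(spes)} detected, {len(truth.spe_times)} injected, "
      f"recall {recall:.2f}")
labels, k_star, scores = neural.cluster_spes(spes, roi.n_rois, rng=0)
print(f"ensemble clustering: k* = {k_star} "
      f"(generator used {cfg.n_ensembles} ensembles), "
      f"silhouette {scores[k_star]:.2f}")

# --- place maps and decoding -------------------------------------------
cfg2 = synth.decoder_regime(seed=4)
trace2, _, truth2 = synth.synth_behavior_session(cfg2)
roi2, truth2 = synth.synth_neural_session(trace2, truth2, cfg2)
maps = neural.compute_rate_maps(roi2.spikes, trace2.x, trace2.y,
                                roi2.frame_rate)
errs = []
for m, (cx, cy) in zip(maps, truth2.field_centers):
    px, py = m.peak_xy()
    errs.append(np.hypot(px - cx, py - cy))
print(f"place maps: median peak-to-truth distance {np.median(errs):.1f} cm")

fr = roi2.frame_rate
windows = [(int(a * fr), int(b * fr))
           for a, b in zip(truth2.trial_start, truth2.trial_stop)]
F, K = neural.build_position_dataset(roi2.spikes, trace2.x, trace2.y, windows)
perm = np.random.default_rng(0).permutation(len(F))
split = int(0.8 * len(F))
model = neural.train_consensus_decoder(
    [F[i] for i in perm[:split]], [K[i] for i in perm[:split]],
    n_folds=50, trials_per_fold=75, rng=1,
)
te_F = np.concatenate([F[i] for i in perm[split:]])
te_K = np.concatenate([K[i] for i in perm[split:]])
r2 = neural.decode_and_score(model, te_F, te_K)
r2s = neural.decode_and_score(model, te_F, te_K, shuffle=True,
                              rng=np.random.default_rng(2))
print(f"consensus decoder: held-out R^2 (x, y) = ({r2[0]:.2f}, {r2[1]:.2f}); "
      f"permuted-weight control = ({r2s[0]:.2f}, {r2s[1]:.2f})")
print("High R^2 with a collapsed shuffle control shows the decoder reads")
print("real positional structure, not dimensionality.")
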