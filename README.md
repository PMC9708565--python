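# foragerl

Reinforcement-learning simulation of foraging-trajectory adaptation, with
the behavioral and hippocampal population-imaging analyses needed to study
it — all validated against a synthetic-data generator with known ground
truth.

## The problem

A mouse foraging from a home port learns to run to a hidden target area
and re-scales its trajectory within tens of trials when the target moves;
the same kind of amplitude adaptation appears in a head-fixed joystick
task.  Dorsal-CA1 populations emit brief synchronous population events
(SPEs, the imaging correlate of sharp-wave-ripple reactivation) whose
timing — after trajectory completion in the arena, before movement
initiation at the joystick — suggests they carry the update signal for
this learning.  This package implements, as testable code:

* a **trajectory-learning agent**: heading and speed control signals
  (`Theta(t) = L(-pi, pi) + omega_i + eps`,
  `S(t) = G(tau, sigma) * a_i + eps`) whose amplitude gain `A` and heading
  offset `Omega` are updated trial-by-trial with a mean-shift-plus-
  homeostasis rule

      A[i+1] = A[i] + alpha * (a[i] - A[i]) * upsilon[i] - beta * (a[i] - A[0])

  where `upsilon` is a smoothed local reward rate — plus four
  inactivation variants of the update (policy reversion, undetected
  reward, 10x biased and attenuated updates) and a hazard-function model
  of SPE-gated movement initiation (`H = g/(1 - G)`, `g = N(3.0, 0.48)` s);
* **task environments**: a 75 x 75 cm arena with 18 x 14 cm hidden targets
  at 34 / 52 cm from the reward port, and a radial joystick target band
  with 100 ms occupancy and 1 s reward delay;
* **behavioral analysis**: Savitzky-Golay preprocessing, attempt
  segmentation (10 cm / 1 s), switch-aligned learning curves, grid-search
  fitting of (alpha, sigma_a), prior-trial-conditioned learning deltas
  with Kruskal-Wallis statistics, and a bootstrap PETH for inactivation
  catch trials;
* **population analysis**: SPE detection (>= 15% of ROIs within ~200 ms),
  ensemble clustering with silhouette selection, SPE-window PCA loadings,
  occupancy-normalised place maps (4 cm bins, 4 cm smoothing), response
  reliability, peri-movement ROI sorting, a consensus pseudoinverse
  position decoder (mean of 50 folds of 75 trials), and cross-day ROI
  matching (footprint correlation > 0.8);
* a **synthetic generator** producing both behavioral sessions and aligned
  ROI activity (place fields, heavy-tailed rates, injected SPEs with
  retrospective or prospective timing) with complete ground truth.

## Worked example

`python examples/run_simulation.py` simulates one two-block arena session
(near target, then far target) and prints:

```
block 1 target at 34 cm, block 2 target at 52 cm
  block 1, trials 60-80: mean amplitude  41.4 cm, P(hit) 0.75
  block 2, trials +0..+10: mean amplitude  35.8 cm, P(hit) 0.20
  block 2, trials +30..+40: mean amplitude  53.9 cm, P(hit) 0.90
  block 2, trials +70..+80: mean amplitude  53.2 cm, P(hit) 1.00
Policy gain A went from 36.0 to 50.8 over the session.
```

The amplitude climbs from the near-target reach toward the far target
within a few tens of trials after the switch — the reward-rate-gated mean
shift dragging the policy toward executed reaches that intercept the new
target — and interception probability recovers accordingly.

The other examples each demonstrate one capability with the numbers it
computes: `perturbation_analysis.py` (conditional deltas under simulated
SPE-timed inactivation), `initiation_hazard.py` (latency distribution and
inactivation delays), `fit_learning_rate.py` (grid-search fitting),
`spe_and_decoding.py` (SPE detection/clustering, place-map recovery and
consensus decoding against ground truth).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — an agent session
with the behavioral pipeline, the initiation model, and a synthetic
imaging session through SPE detection, place-map recovery and consensus
decoding — printing summary statistics along the way and writing the
results JSON to `--out`.  The quantitative contracts of the package (the
learning rule's fixed points, the hazard-construction identity, detection
and recovery rates, decoder and null-calibration bounds) live in
`tests/test_acceptance.py`, one test each.

## Layout

```
src/foragerl/
  envsim.py    task geometry, reward rules, block schedules
  agent.py     trajectory generation, MeSH rule, perturbations,
               initiation hazard, Q baseline
  fitting.py   switch-aligned curves, grid-search fitting
  behavior.py  preprocessing, attempts, deltas, PETH bootstrap
  neural.py    SPEs, place maps, sorting, decoding, ROI matching
  synth.py     synthetic sessions with ground truth
  io.py        session CSV, RoiMatrix HDF5, YAML configs, manifests
examples/      one narrative script per capability
docs/methods.md  models, defaults, and what green tests do (not) establish
```
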