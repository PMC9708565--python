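# Methods

This note documents the models and analysis procedures implemented in
`foragerl`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## The trajectory-learning agent

### Generative kinematics

A foraging trajectory is generated from two control signals sampled at
`dt` (default 0.01 s):

    Theta(t) = L(-pi, pi) + omega_i + eps_theta      (heading)
    S(t)     = G(tau, sigma) * a_i + eps_s           (speed)

`L` is a linear sweep of heading across a full turn, which together with a
bell-shaped speed profile produces a roughly elliptical out-and-back loop;
`G` is a sum of Gaussian bumps at peak times `tau` — two bumps (outward and
return run) for the arena task, one for the joystick task.  Position is the
path integral of speed along the heading.  The loop is not constrained to
close; with the default arena shape (duration 4 s, peaks at 1 s and 3 s,
sigma 0.5 s) it closes to within ~5% of the maximum excursion, which is
reported as a diagnostic only — all analyses use the maximum radial
amplitude and heading, not closure.

The noiseless maximum excursion is exactly linear in the gain `a_i`
(`calibrate_shape` returns the cm-per-gain constant and the excursion
direction; default policies aim the excursion at the target axis).  The
noise terms are white Gaussian smoothed with a 0.15 s box-car; their
amplitudes (0.1 rad heading, 2 cm/s speed) give a modest within-trajectory
wobble, and combined with the trial-to-trial gain sampling the total
max-amplitude CV is ~0.18.

### The learning rule (mean shift + homeostasis)

Each trial the agent executes `a_i ~ N(A, sigma_a)` and
`omega_i ~ N(Omega, sigma_omega)` and updates

    A      <- A + alpha * (a_i - A) * upsilon_i - beta * (a_i - A0)
    Omega  <- likewise, with circular differences

where `upsilon_i` is an exponentially smoothed local reward rate
(`upsilon_i = (1 - lambda) upsilon_{i-1} + lambda R_i`).  Two ordering /
arithmetic decisions matter:

* **`upsilon` includes the current trial's outcome.**  The mean shift then
  has expectation `alpha * lambda * Cov(R_i, a_i)`: executed gains that
  earn reward pull the policy toward themselves.  With `upsilon` computed
  from past trials only, `E[dA] = -beta (A - A0)` regardless of the reward
  contingency and the agent could never climb toward a target above its
  default — so the inclusive ordering is the only one under which the rule
  functions as a learning rule.
* **Heading differences are wrapped to (-pi, pi].**  The default heading
  offset sits near +pi (the excursion axis), where raw differences jump by
  ~2 pi whenever a sampled offset wraps; circular differences make the
  update continuous on the circle.

Defaults: `alpha = 0.5`, `beta = 0.03`, `lambda = 0.5`,
`sigma_a = 0.3 * A0`, `sigma_omega = 0.1`, and an innate amplitude `A0`
equivalent to a 34 cm reach (the near-target distance — sessions model
trained animals whose baseline excursions match the first block).  These
were fixed once, by requiring that the stated world reproduce the defining
phenomenon of the task — amplitude re-scaling to a switched target within
tens of trials — and are not revisited per analysis.  The dynamics are a
reward-gated ratchet: after a switch, rewards stop, `upsilon` decays and
updates freeze near the old policy; an occasional far reach that intercepts
the new target re-opens the gate and consecutive rewarded reaches compound
the shift.  Smaller `lambda` or larger `beta` break the ratchet (the agent
relaxes to default before it can climb).

### Perturbation variants

Four implementations of impaired updating, applied on masked (laser) trials:
reversion of the policy to its default (`default_policy`); recomputing the
update as if the reward had gone undetected (`reward_not_detected`; the
smoothed reward rate follows the undetected outcome too); scaling the MeSH
increment by 10 (`learning_bias`); scaling it by a gain in [0, 0.1]
(`reduced_learning`, default 0.05 — the interval midpoint).

A structural consequence of the arena reward rule (reward on *any*
crossing of the target rectangle, so over-shoots still score): amplitude
misses are one-sided, unrewarded trials select low executed gains, and the
conditional amplitude delta after unrewarded trials is positive (regression
to the mean) rather than negative (homeostatic contraction).  The
reversion signature after laser trials is therefore clearly separable from
the rewarded condition but is *not* statistically indistinguishable from
the unrewarded condition in this world; making the unrewarded delta
negative would require a homeostatic rate large enough to abolish switch
adaptation.  Both facts are asserted as-is in the acceptance suite (one
red sub-claim, by design not tuned away).

### Movement initiation

Self-initiated movement times follow a hazard
`H(t) = g(t) / (1 - G(t))` with `g = N(3.0 s, 0.48 s)`; sampling a uniform
variable against `H dt` per step reproduces `g` (truncated at zero)
exactly in the small-`dt` limit (initiation grid `dt = 5 ms`; the KS
identity is part of the acceptance suite).  An optional SPE gate requires
a synchronous population event before initiation — either any SPE since
the window start (latched, default) or one within the last 0.5 s
(sliding; an eligibility trace that decays).  SPEs arrive as a renewal
process (default exponential, 0.5 Hz; any interval sampler can be
plugged in).  Simulated inactivation thins SPEs inside laser windows to
25% of baseline and emits a rebound SPE at laser offset with probability
0.9.

A consequence worth stating: the rebound event is a *reliable, well-timed*
gate opener.  A short inactivation (~1 s) therefore does not delay mean
initiation — it can slightly accelerate it by rescuing trials whose
spontaneous first SPE would have come late — and the delay-vs-duration
curve is monotone only from ~2 s upward, once the laser covers the bulk of
the latency density.  The acceptance criterion asserting strict
monotonicity across {0, 1, 2, 4} s is left red with this mechanism as the
explanation; configurations that would pass (faster SPE rates than either
rate stated for the modelled system) were not adopted post hoc.

### Epsilon-greedy Q baseline

A converged tabular value function (negative shortest-path distance to the
goal on a 3 cm, 8-connected grid) with epsilon-greedy action selection.
Epsilon 0 walks the shortest path to the old target and never reaches a
switched target; epsilon 1 is a random walk (RMS displacement growing as
the square root of steps).  Used only as a contrast to the
trajectory-learning agent.

## Fitting

The observable is the switch-aligned mean max-amplitude curve (offsets
-10..+40 around the switch).  `grid_search_fit` simulates sessions on a
5 x 5 grid over (alpha, sigma_a/A0), using common random numbers across
pairs, and minimises by default a joint loss — amplitude-curve MSE plus
interception-rate-curve MSE, each normalised by the observed curve's
variance.  The hit-rate term was added because amplitude alone leaves an
(alpha, sigma_a) trade-off under-determined; a plain amplitude MSE is
available by option.  Identifiability is intrinsically limited: with
20-session observed curves, the sampling noise of the observation exceeds
the separation between adjacent grid cells, so the argmin lands on the
generating cell only ~60% of the time (always within one grid step).

## Behavioral analysis

Position traces are despiked (single-frame jumps beyond a threshold,
linear interpolation) and smoothed with a 3rd-order, 11-point
Savitzky-Golay filter.  Attempts are maximal radial excursions reaching
10 cm for at least 1 s, with hysteresis boundaries at 10% of threshold;
max amplitude is taken over the first 500 ms (guards against long
perimeter-hugging trajectories); initial heading is the angle of the first
500 ms displacement from the +y axis; joystick movements are detected by a
2 mm/s speed threshold with 1 s minimum duration and separation.
Trial-to-trial deltas are conditioned on the prior attempt (unrewarded /
rewarded / rewarded + laser, the laser flag extending 2 s past attempt
stop into the collection window) and compared across conditions with a
Kruskal-Wallis omnibus on session-wise means plus Holm-corrected pairwise
Mann-Whitney tests.  The inactivation PETH uses k-out-of-k resampling
(1,000 iterations, 100 ms bins, 12 s window) with percentile 95% CIs, and
marks spans of at least 200 ms where the catch and control CIs are
disjoint; its false-positive rate on null sessions is calibrated in the
acceptance suite (<= 5%).

## Population-imaging analysis

* **SPE detection**: a sliding ~200 ms window counts distinct ROIs with at
  least one deconvolved event; windows where >= 15% of the imaged
  population is active are events, merged at local maxima of the active
  fraction.  The 15% threshold is of all imaged ROIs.
* **Clustering**: k-means (20 restarts) on binary participation vectors,
  k chosen by mean silhouette over k = 2..8.
* **PC loadings**: +/-250 ms dF/F windows around each event are
  concatenated; the leading principal component over ROIs (sign fixed so
  the largest-magnitude weight is positive) gives per-event loadings,
  correlated with behavioral covariates by Pearson r.
* **Place maps**: movement periods (speed >= 1 cm/s), 4 cm bins, bins with
  fewer than 5 entries masked, transients/occupancy, 4 cm Gaussian
  smoothing (mask-normalised), max-normalised.
* **Reliability**: sliding +/-250 ms mean pairwise trial-to-trial Pearson
  correlation of population vectors (the chosen definition; a single-ROI
  trial-consistency variant was considered and not needed).
* **Peri-movement sorting**: cross-validated (sort half the trials by peak
  latency, apply to the held-out half) or hierarchical (median split on
  session-mean activity, then latency; all-equal means fall back to a pure
  latency sort).
* **Consensus decoder**: per fold, `W = pinv(F) K` on 75 randomly chosen
  trials (time-bin rows concatenated); the consensus is the mean of 50
  fold solutions; `R^2` per output channel, with a permuted-weight
  control.  Rank-deficient folds use the minimum-norm solution and are
  logged.
* **Cross-day matching**: greedy one-to-one assignment of footprint pairs
  with spatial Pearson correlation above 0.8, in descending order.

## The synthetic generator

`synth_behavior_session` drives the agent through the task and stitches
trials into a continuous trace (rest at the port for the re-arm delay plus
a Gaussian self-initiation latency; joystick trials get a 0.5 s spring
return), resampled to the imaging frame rate (10 Hz default), with reward
and laser event logs.  `synth_neural_session` adds ROI activity:
inhomogeneous Poisson spikes from Gaussian place fields (centres sampled
from *visited* positions, so every field is recoverable in principle;
width 8 cm; log-normal peak rates, median 5 Hz, sigma_log 1 — a
heavy-tailed activation propensity) or movement-phase tuning for the
joystick task; SPEs injected at 0.5 Hz within eligible windows (2 s after
trajectory stop, or 2 s before movement onset in prospective mode), each
recruiting 20% of ROIs from a small set of recurring ensembles, optionally
tied to a behavioral covariate; dF/F is the spikes convolved with a 0.5 s
exponential (GCaMP6f-like) plus 0.1 noise.

What the generator does **not** emulate: imaging artefacts
(photobleaching, motion, crosstalk), biophysical calcium dynamics,
theta-timescale structure inside movements, and realistic variation of
field counts per cell (one field per ROI).  A green test therefore
establishes that an analysis recovers the stated structure at the stated
noise level, not that it is robust to everything real imaging adds.

Two named regimes sharpen specific positive controls: `spe_regime`
removes positional tuning (sparse 0.1 Hz background) so detection
recall/false-alarm rates are well-defined; `decoder_regime` uses 400 ROIs
at 60 Hz median peak rate — deliberately above calcium event rates — so
the decoder contract tests linear decodability rather than shot noise.

## Numerical and degenerate-input conventions

Initiation sampling clamps `H dt` to [0, 1] and caps the survival grid at
the trial window (no initiation -> None/NaN).  Kruskal-Wallis on
all-identical values returns H = 0, p = 1 rather than NaN.  All stochastic
operations accept a seed or Generator and are bit-reproducible;
`run_session` pre-draws its randomness so results do not depend on
incidental evaluation order.  Empty footprints, zero-variance covariates,
zero attempts and empty rasters raise explicit errors rather than
propagating NaN.
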