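"""Grid-search fit of the learning rate and exploration s.d.

Treats a batch of simulated sessions as the "observed" behavior, builds
the switch-aligned amplitude curve, and fits (alpha, sigma_a) by grid
search: for every pair on a 5 x 5 grid, sessions are re-simulated and
compared to the observed curve with a joint amplitude + hit-rate loss.
A small 3 x 3 grid keeps this demonstration quick.
"""

import numpy as np

from foragerl import agent, fitting

pol = agent.default_stf_policy()
true_alpha, true_frac = 0.4, 0.2
print(f"generating 'observed' sessions at alpha={true_alpha}, "
      f"sigma_a={true_frac:.2f}*A0 ...")
observed = fitting.simulate_switch_curve(
    true_alpha, true_frac * pol.A0, 12, np.random.default_rng(1)
)

fit = fitting.grid_search_fit(
    observed,
    alphas=(0.2, 0.4, 0.8),
    sigma_fracs=(0.1, 0.2, 0.3),
    n_sims=10,
    seed=7,
)
print("loss surface (rows alpha, cols sigma_a/A0):")
for i, a in enumerate((0.2, 0.4, 0.8)):
    row = fit.loss_surface[3 * i:3 * i + 3]
    print(f"  alpha={a}: " + "  ".join(f"{v:7.3f}" for v in row))
print(f"best pair: alpha={fit.best_pair[0]}, sigma_a={fit.best_pair[1]}*A0 "
      f"(truth: {true_alpha}, {true_frac})")
print("The minimum should sit at or next to the generating parameters.")
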