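"""Generative kinematics, the MeSH rule, perturbations, sessions, Q baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragerl import agent as ag
from foragerl.envsim import ArenaSpec, BlockSchedule


SHAPE = ag.default_stf_shape()


class TestHeading:
    def test_noiseless_linear_sweep_endpoints(self):
        th = ag.generate_heading(SHAPE, 0.0)
        assert th[0] == pytest.approx(-np.pi)
        assert th[-1] == pytest.approx(np.pi)
        assert th[len(th) // 2] == pytest.approx(0.0, abs=1e-9)

    def test_offset_is_additive(self):
        base = ag.generate_heading(SHAPE, 0.0)
        shifted = ag.generate_heading(SHAPE, np.pi / 4)
        np.testing.assert_allclose(shifted - base, np.pi / 4)

    def test_noise_is_zero_mean(self, rng):
        """Monte-Carlo: the mean noisy series converges on the noiseless one."""
        noise = ag.NoiseSpec(amplitude=0.3)
        base = ag.generate_heading(SHAPE, 0.0)
        n = 2000
        acc = np.zeros_like(base)
        for _ in range(n):
            acc += ag.generate_heading(SHAPE, 0.0, noise, rng)
        mean = acc / n
        # pointwise s.e. ~ amplitude / sqrt(n); allow 5 s.e.
        assert np.max(np.abs(mean - base)) < 5 * 0.3 / np.sqrt(n)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ag.TrajectoryShape(tau=(1.0,), sigma=0.5, duration=-1.0)


class TestSpeed:
    def test_zero_gain_gives_zero_series(self):
        assert not ag.generate_speed(SHAPE, 0.0).any()

    def test_linearity_in_gain(self):
        s1 = ag.generate_speed(SHAPE, 1.3)
        s2 = ag.generate_speed(SHAPE, 2.6)
        np.testing.assert_allclose(s2, 2 * s1)

    def test_two_local_maxima_at_peak_times(self):
        shape = ag.TrajectoryShape(tau=(1.0, 3.0), sigma=0.5, duration=4.0)
        s = ag.generate_speed(shape, 1.0)
        t = shape.times()
        # numeric argmax within each half matches the stated peak times
        for tau, sl in [(1.0, t < 2.0), (3.0, t >= 2.0)]:
            k = np.argmax(np.where(sl, s, -np.inf))
            assert abs(t[k] - tau) <= shape.dt + 1e-12

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            ag.generate_speed(SHAPE, -0.1)


class TestIntegration:
    def test_zero_speed_stays_at_origin(self):
        n = 100
        traj = ag.integrate_trajectory(np.zeros(n), np.zeros(n), (3.0, 4.0))
        np.testing.assert_allclose(traj, np.tile([3.0, 4.0], (n + 1, 1)))

    def test_constant_heading_gives_straight_segment(self):
        n, v, dt = 200, 2.5, 0.01
        traj = ag.integrate_trajectory(
            np.full(n, np.pi / 2), np.full(n, v), (0, 0), dt
        )
        np.testing.assert_allclose(traj[:, 0], 0.0, atol=1e-12)
        assert traj[-1, 1] == pytest.approx(v * n * dt)

    def test_default_loop_nearly_closes(self):
        """Out-and-back double-Gaussian loop returns close to the origin."""
        h = ag.generate_heading(SHAPE, 0.0)
        s = ag.generate_speed(SHAPE, 1.0)
        traj = ag.integrate_trajectory(h, s, (0, 0), SHAPE.dt)
        r = np.hypot(traj[:, 0], traj[:, 1])
        # closure is a diagnostic, not an enforced constraint: the default
        # shape closes to ~5% of the maximum excursion
        assert np.hypot(*traj[-1]) <= 0.06 * r.max()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ag.integrate_trajectory(np.zeros(5), np.zeros(6))

    def test_amplitude_linear_in_gain(self):
        """Noiseless max radial excursion is proportional to the gain."""
        gains = np.linspace(0.5, 3.0, 8)
        h = ag.generate_heading(SHAPE, 0.0)
        amps = []
        for a in gains:
            traj = ag.integrate_trajectory(
                h, ag.generate_speed(SHAPE, a), (0, 0), SHAPE.dt
            )
            amps.append(np.hypot(traj[:, 0], traj[:, 1]).max())
        r = np.corrcoef(gains, amps)[0, 1]
        assert r**2 > 0.999


class TestRewardRate:
    @pytest.mark.parametrize(
        "prev,lam,rew,expect",
        [(0.0, 1.0, True, 1.0), (0.5, 0.3, False, 0.35), (1.0, 0.2, True, 1.0)],
    )
    def test_substitution(self, prev, lam, rew, expect):
        assert ag.update_reward_rate(prev, rew, lam) == pytest.approx(expect)

    def test_constant_rewards_converge_geometrically(self):
        u, lam = 0.0, 0.4
        for i in range(1, 20):
            u = ag.update_reward_rate(u, True, lam)
            assert 1.0 - u == pytest.approx((1 - lam) ** i)

    @given(
        prev=st.floats(0, 1), lam=st.floats(0.01, 1.0),
        rew=st.booleans(),
    )
    @settings(deadline=None, max_examples=50)
    def test_stays_in_unit_interval(self, prev, lam, rew):
        assert 0.0 <= ag.update_reward_rate(prev, rew, lam) <= 1.0

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            ag.update_reward_rate(0.5, True, 0.0)


class TestMeshRule:
    POLICY = ag.PolicyState(A=1.0, Omega=0.0, A0=1.0, Omega0=0.0,
                            sigma_a=0.1, sigma_omega=0.1)

    def test_fixed_point_when_executed_equals_policy_and_default(self):
        p = self.POLICY
        out = ag.mesh_update(p, 1.0, 0.0, 0.7, ag.MeshParams(0.5, 0.2, 0.5))
        assert out.A == p.A and out.Omega == p.Omega

    def test_mean_shift_substitution(self):
        # A=1, a=2, upsilon=1, alpha=0.5, beta=0 -> A' = 1.5 exactly
        out = ag.mesh_update(
            self.POLICY, 2.0, 0.0, 1.0, ag.MeshParams(0.5, 0.0, 0.5)
        )
        assert out.A == 1.5

    def test_homeostatic_substitution(self):
        # A=2, a=2, A0=1, upsilon=0, beta=0.1 -> A' = 1.9 exactly
        p = ag.PolicyState(A=2.0, Omega=0.0, A0=1.0, Omega0=0.0,
                           sigma_a=0.1, sigma_omega=0.1)
        out = ag.mesh_update(p, 2.0, 0.0, 0.0, ag.MeshParams(0.5, 0.1, 0.5))
        assert out.A == 1.9

    def test_homeostatic_relaxation_factor(self):
        """With upsilon = 0 and beta = 0.1, E[A] relaxes to A0 by 0.9/trial."""
        p = ag.PolicyState(A=3.0, Omega=0.0, A0=1.0, Omega0=0.0,
                           sigma_a=0.0, sigma_omega=0.0)
        params = ag.MeshParams(alpha=0.5, beta=0.1, reward_smoothing=0.5)
        gap = p.A - p.A0
        for i in range(1, 101):
            p = ag.mesh_update(p, p.A, 0.0, 0.0, params)
            expect = 1.0 + gap * 0.9**i
            assert abs(p.A - expect) / expect < 1e-9

    def test_heading_update_wraps_on_circle(self):
        """An offset near +pi updates continuously across the wrap point."""
        p = ag.PolicyState(A=1.0, Omega=3.1, A0=1.0, Omega0=3.1,
                           sigma_a=0.1, sigma_omega=0.1)
        # executed heading wrapped to the other side of +/-pi
        out = ag.mesh_update(p, 1.0, -3.1, 1.0, ag.MeshParams(0.5, 0.0, 0.5))
        # circular distance 2*pi - 6.2 ~ 0.083; half of it applied
        expect = 3.1 + 0.5 * (2 * np.pi - 6.2)
        circ_err = (out.Omega - expect + np.pi) % (2 * np.pi) - np.pi
        assert abs(circ_err) < 1e-9

    def test_mean_shift_drives_amplitude_up_under_selective_reward(self, rng):
        """Reward contingent on a exceeding the policy mean raises A."""
        wins = 0
        n_sessions = 60
        for _ in range(n_sessions):
            p = ag.PolicyState(A=1.0, Omega=0.0, A0=1.0, Omega0=0.0,
                               sigma_a=0.3, sigma_omega=0.0)
            u = 0.0
            for _ in range(60):
                a = max(p.A + p.sigma_a * rng.standard_normal(), 0.0)
                rewarded = a > p.A  # threshold above the current mean
                u = ag.update_reward_rate(rewarded, rewarded, 0.5) if False \
                    else ag.update_reward_rate(u, rewarded, 0.5)
                p = ag.mesh_update(p, a, 0.0, u, ag.MeshParams(0.3, 0.0, 0.5))
            wins += p.A > 1.0
        # one-sided sign test: under drift-free dynamics wins ~ Bin(n, 0.5)
        from scipy.stats import binomtest
        assert binomtest(wins, n_sessions, alternative="greater").pvalue < 0.01


class TestPerturbations:
    BEFORE = ag.PolicyState(A=2.0, Omega=0.3, A0=1.0, Omega0=0.0,
                            sigma_a=0.1, sigma_omega=0.1)
    AFTER = ag.PolicyState(A=2.05, Omega=0.32, A0=1.0, Omega0=0.0,
                           sigma_a=0.1, sigma_omega=0.1)

    def test_none_is_identity(self):
        spec = ag.PerturbationSpec("none", trial_mask={3})
        assert ag.apply_perturbation(self.BEFORE, self.AFTER, spec, 3) \
            == self.AFTER

    def test_unmasked_trial_unchanged(self):
        spec = ag.PerturbationSpec("default_policy", trial_mask={5})
        assert ag.apply_perturbation(self.BEFORE, self.AFTER, spec, 3) \
            == self.AFTER

    def test_default_policy_reverts_to_defaults(self):
        spec = ag.PerturbationSpec("default_policy", trial_mask={3})
        out = ag.apply_perturbation(self.BEFORE, self.AFTER, spec, 3)
        assert out.A == self.BEFORE.A0 and out.Omega == self.BEFORE.Omega0

    def test_learning_bias_scales_increment_tenfold(self):
        before = ag.PolicyState(A=1.0, Omega=0.0, A0=1.0, Omega0=0.0,
                                sigma_a=0.1, sigma_omega=0.1)
        after = ag.PolicyState(A=1.05, Omega=0.0, A0=1.0, Omega0=0.0,
                               sigma_a=0.1, sigma_omega=0.1)
        spec = ag.PerturbationSpec("learning_bias", trial_mask={0})
        out = ag.apply_perturbation(before, after, spec, 0)
        assert out.A == pytest.approx(1.5)

    def test_reduced_learning_attenuates_increment(self):
        spec = ag.PerturbationSpec("reduced_learning", gain=0.05,
                                   trial_mask={0})
        out = ag.apply_perturbation(self.BEFORE, self.AFTER, spec, 0)
        assert out.A == pytest.approx(2.0 + 0.05 * 0.05)

    def test_reward_not_detected_requires_recomputed_state(self):
        spec = ag.PerturbationSpec("reward_not_detected", trial_mask={0})
        with pytest.raises(ValueError, match="unrewarded"):
            ag.apply_perturbation(self.BEFORE, self.AFTER, spec, 0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ag.PerturbationSpec("zap_everything")

    def test_reduced_learning_gain_bounds(self):
        with pytest.raises(ValueError):
            ag.PerturbationSpec("reduced_learning", gain=0.5)


class TestSession:
    def test_zero_rates_freeze_policy(self):
        res = ag.run_session(
            ArenaSpec(), BlockSchedule(((1, 15),)), ag.default_stf_policy(),
            SHAPE, ag.MeshParams(alpha=0.0, beta=0.0, reward_smoothing=0.5),
            seed=0, keep_trajectories=False,
        )
        assert len(set((p.A, p.Omega) for p in res.policy_history)) == 1

    def test_same_seed_is_bitwise_identical(self):
        kw = dict(
            heading_noise=ag.DEFAULT_HEADING_NOISE,
            speed_noise=ag.DEFAULT_SPEED_NOISE, seed=7,
        )
        r1 = ag.run_session(ArenaSpec(), BlockSchedule(((1, 10),)),
                            ag.default_stf_policy(), SHAPE, ag.MeshParams(), **kw)
        r2 = ag.run_session(ArenaSpec(), BlockSchedule(((1, 10),)),
                            ag.default_stf_policy(), SHAPE, ag.MeshParams(), **kw)
        for t1, t2 in zip(r1.trials, r2.trials):
            assert t1.a == t2.a and t1.max_amplitude == t2.max_amplitude
            np.testing.assert_array_equal(t1.trajectory, t2.trajectory)

    def test_policy_history_length_invariant(self):
        res = ag.run_session(
            ArenaSpec(), BlockSchedule(((1, 8),)), ag.default_stf_policy(),
            SHAPE, ag.MeshParams(), seed=1, keep_trajectories=False,
        )
        assert len(res.policy_history) == len(res.trials) + 1

    def test_far_switch_raises_late_block_amplitude(self):
        """After a near-to-far switch, late block-2 amplitudes exceed late
        block-1 amplitudes in most sessions (reward structure forces it)."""
        ups = 0
        for seed in range(8):
            res = ag.run_session(
                ArenaSpec(), BlockSchedule(((1, 80), (2, 80))),
                ag.default_stf_policy(), SHAPE, ag.MeshParams(),
                heading_noise=ag.DEFAULT_HEADING_NOISE,
                speed_noise=ag.DEFAULT_SPEED_NOISE,
                seed=seed, keep_trajectories=False,
            )
            a = res.amplitudes()
            ups += a[150:160].mean() > a[70:80].mean()
        assert ups >= 6

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            BlockSchedule(())

    def test_ntf_session_freezes_heading(self):
        from foragerl.envsim import JoystickSpec
        res = ag.run_session(
            JoystickSpec(), BlockSchedule(((1, 10),)),
            ag.default_ntf_policy(), ag.default_ntf_shape(), ag.MeshParams(),
            seed=2, keep_trajectories=False,
        )
        assert all(p.Omega == res.policy_history[0].Omega
                   for p in res.policy_history)


class TestQBaseline:
    def test_greedy_agent_takes_shortest_path_and_misses_new_target(self):
        arena = ArenaSpec()
        trajs = ag.run_q_baseline(arena, epsilon=0.0, n_trajectories=3, seed=0,
                                  goal_target=1)
        far = arena.target_rects[2]
        for tr in trajs:
            # terminates inside the old (goal) target
            assert arena.target_rects[1].contains(*tr[-1])
            # a converged greedy agent never visits the new, farther target
            assert not far.contains(tr[:, 0], tr[:, 1]).any()
            # path length equals the BFS shortest path (no detours)
            steps = len(tr) - 1
            assert steps <= 13  # chebyshev distance port->target-1 at 3 cm cells

    def test_random_walk_rms_grows_like_sqrt_steps(self):
        arena = ArenaSpec(width=300.0, height=300.0,
                          collection_rect=None or ArenaSpec().collection_rect,
                          target_rects={1: ArenaSpec().target_rects[1]})
        trajs = ag.run_q_baseline(arena, epsilon=1.0, n_trajectories=200,
                                  seed=1, goal_target=1, step_cap=400)
        start = trajs[0][0]
        def rms(k):
            d = [np.hypot(*(t[k] - start)) for t in trajs if len(t) > k]
            return np.sqrt(np.mean(np.square(d)))
        ratio = rms(400) / rms(100)
        assert ratio == pytest.approx(2.0, rel=0.25)  # sqrt(4) scaling

    def test_epsilon_fraction_of_steps_is_greedy(self):
        """With epsilon = 0.1, ~90% of steps decrease distance-to-goal."""
        arena = ArenaSpec()
        trajs = ag.run_q_baseline(arena, epsilon=0.1, n_trajectories=400,
                                  seed=2, goal_target=1)
        goal = np.asarray(arena.target_rects[1].center)
        greedy = total = 0
        for tr in trajs:
            d = np.linalg.norm(tr - goal, axis=1)
            greedy += np.sum(np.diff(d) < 0)
            total += len(d) - 1
        # greedy steps always reduce distance; 1/8 of random steps do too
        assert greedy / total > 0.85

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            ag.run_q_baseline(ArenaSpec(), epsilon=1.5, n_trajectories=1)
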