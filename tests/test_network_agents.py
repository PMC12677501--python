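import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qbehave.agents import (
    AgentCheckpoint,
    TabularMDPEnv,
    TrainConfig,
    analytic_two_action_mdp,
    epsilon_greedy,
    evaluate_score,
    random_mdp,
    td_target,
    train_agent,
    value_iteration_oracle,
)
from qbehave.exceptions import QBehaveError, ShapeMismatchError
from qbehave.network import (
    QNetwork,
    QNetworkConfig,
    RecurrentState,
    dueling_combine,
    mini_config,
)
from qbehave.synthetic_data import MiniCatch
from .conftest import fresh_checkpoint


class TestQValues:
    def test_zero_weights_give_zero_q(self):
        cfg = mini_config("baseline")
        net = QNetwork(cfg, seed=0)
        for k in net.params:
            net.params[k][:] = 0.0
        q, _, _ = net.q_values(np.random.default_rng(0).random((4, 12, 12)))
        assert np.array_equal(q, np.zeros(cfg.n_actions))

    def test_output_length_matches_n_actions(self):
        for variant in ("baseline", "dueling_double", "recurrent"):
            cfg = mini_config(variant, n_actions=5)
            net = QNetwork(cfg, seed=1)
            state = RecurrentState.zeros(cfg) if variant == "recurrent" else None
            q, _, _ = net.q_values(np.zeros((4, 12, 12)), state)
            assert q.shape == (5,)

    def test_manual_forward_on_three_parameter_network(self):
        """1x1 input, one conv weight w, hand-set linear head: Q by hand algebra."""
        cfg = QNetworkConfig(n_actions=2, variant="baseline", conv_specs=((1, 1, 1),),
                             fc_width=1, input_frames=1, input_size=1)
        net = QNetwork(cfg, seed=0)
        w, a, h1, h2 = 3.0, 2.0, 0.5, -1.5
        net.params["conv0_w"][:] = w
        net.params["conv0_b"][:] = 0.0
        net.params["fc_w"][:] = a
        net.params["fc_b"][:] = 0.0
        net.params["out_w"][:] = np.array([[h1, h2]])
        net.params["out_b"][:] = 0.0
        x = np.full((1, 1, 1), 0.25)
        q, _, _ = net.q_values(x)
        hidden = max(w * 0.25, 0) * a  # conv -> relu -> fc -> relu (positive path)
        assert np.allclose(q, [h1 * hidden, h2 * hidden])

    def test_shape_mismatch_named_error(self):
        net = QNetwork(mini_config("baseline"), seed=0)
        with pytest.raises(ShapeMismatchError):
            net.q_values(np.zeros((4, 10, 10)))

    def test_recurrent_requires_state(self):
        net = QNetwork(mini_config("recurrent"), seed=0)
        with pytest.raises(ShapeMismatchError):
            net.q_values(np.zeros((4, 12, 12)))


class TestDuelingCombine:
    def test_mean_advantage_cancels(self):
        assert np.allclose(dueling_combine(2.0, np.array([1.0, 2.0, 3.0])), [1, 2, 3])

    def test_constant_advantages_give_state_value(self):
        assert np.allclose(dueling_combine(4.0, np.full(3, 7.0)), [4, 4, 4])

    def test_mean_subtraction(self):
        assert np.allclose(dueling_combine(0.0, np.array([0.0, 3.0])), [-1.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-10, 10), st.lists(st.floats(-10, 10), min_size=2, max_size=6),
           st.floats(-100, 100))
    def test_invariant_to_constant_shift(self, v, adv, c):
        adv = np.array(adv)
        assert np.allclose(dueling_combine(v, adv), dueling_combine(v, adv + c), atol=1e-9)


class _FakeNet:
    def __init__(self, q):
        self.q = np.asarray(q, dtype=float)

    def q_values(self, stacks, rec_state=None, keep_cache=False):
        n = 1 if np.asarray(stacks).ndim == 3 else np.asarray(stacks).shape[0]
        return np.tile(self.q, (n, 1)), None, None


class TestTdTarget:
    def test_terminal_is_reward_only(self):
        net = _FakeNet([2.0, 5.0])
        assert td_target(1.0, True, np.zeros((4, 12, 12)), 0.99, False, net, net) == 1.0

    def test_vanilla_bootstraps_from_max(self):
        target = _FakeNet([2.0, 5.0])
        y = td_target(1.0, False, np.zeros((4, 12, 12)), 0.99, False, target, target)
        assert np.isclose(y, 1 + 0.99 * 5)

    def test_double_decouples_selection_from_evaluation(self):
        online = _FakeNet([10.0, 1.0])  # argmax -> action 0
        target = _FakeNet([2.0, 5.0])
        y = td_target(1.0, False, np.zeros((4, 12, 12)), 0.99, True, online, target)
        assert np.isclose(y, 1 + 0.99 * 2)

    def test_double_equals_vanilla_when_nets_agree(self, rng):
        q = rng.normal(size=2)
        net = _FakeNet(q)
        a = td_target(0.3, False, np.zeros((4, 12, 12)), 0.9, False, net, net)
        b = td_target(0.3, False, np.zeros((4, 12, 12)), 0.9, True, net, net)
        assert np.isclose(a, b)


class TestEpsilonGreedy:
    def test_greedy_takes_argmax(self, rng):
        assert epsilon_greedy(np.array([0.0, 3.0, 1.0]), 0.0, rng) == 1

    def test_tie_break_lowest_index(self, rng):
        assert epsilon_greedy(np.array([2.0, 2.0]), 0.0, rng) == 0

    def test_uniform_when_fully_random(self):
        rng = np.random.default_rng(3)
        q = np.array([0.0, 9.0, 1.0, 2.0])
        draws = np.array([epsilon_greedy(q, 1.0, rng) for _ in range(100_000)])
        freq = np.bincount(draws, minlength=4) / draws.size
        assert np.all(np.abs(freq - 0.25) < 0.01)

    def test_empty_q_rejected(self, rng):
        with pytest.raises(QBehaveError):
            epsilon_greedy(np.array([]), 0.1, rng)


class TestValueIterationOracle:
    def test_self_loop_geometric_series(self):
        P, R = analytic_two_action_mdp()
        q = value_iteration_oracle(P, R, gamma=0.5)
        assert np.allclose(q, [[2.0, 1.0]], atol=1e-9)

    def test_gamma_one_rejected(self):
        P, R = analytic_two_action_mdp()
        with pytest.raises(ValueError):
            value_iteration_oracle(P, R, gamma=1.0)

    def test_bellman_residual_vanishes(self):
        P, R = random_mdp(5, 3, seed=1)
        q = value_iteration_oracle(P, R, gamma=0.9, tol=1e-12)
        residual = R + 0.9 * P @ q.max(axis=1) - q
        assert np.max(np.abs(residual)) < 1e-10


class TestTrainingMachinery:
    def test_checkpoint_roundtrip_bit_exact(self, tmp_path):
        ckpt = fresh_checkpoint("dueling_double", seed=5)
        ckpt.mean_eval_score = 3.25
        ckpt.save(tmp_path / "ckpt")
        loaded = AgentCheckpoint.load(tmp_path / "ckpt")
        x = np.random.default_rng(1).random((4, 12, 12))
        q_a, _, _ = ckpt.to_network().q_values(x)
        q_b, _, _ = loaded.to_network().q_values(x)
        assert np.array_equal(q_a, q_b)
        assert loaded.env_frames_seen == 0 and loaded.mean_eval_score == 3.25

    def test_no_update_until_buffer_reaches_batch(self):
        """With fewer transitions than a batch, weights must stay untouched."""
        P, R = analytic_two_action_mdp()
        env = TabularMDPEnv(P, R, seed=0, frame_size=4)
        qcfg = mini_config("baseline", n_actions=2, input_size=4, input_frames=1)
        tcfg = TrainConfig(total_env_frames=20, batch_size=32, min_replay=0,
                           frame_skip=1, checkpoint_every=10**9, seed=0)
        ckpts = train_agent(env, qcfg, tcfg)
        first, last = ckpts[0].params, ckpts[-1].params
        assert all(np.array_equal(first[k], last[k]) for k in first)

    def test_trained_agent_beats_random_play(self, trained_run):
        random_score = evaluate_score(fresh_checkpoint("dueling_double", seed=123),
                                      MiniCatch(seed=99), n_episodes=50, epsilon=1.0,
                                      seed=7926)
        assert trained_run[-1].mean_eval_score > random_score

    def test_checkpoint_cadence_and_frame_counts(self, trained_run):
        frames = [c.env_frames_seen for c in trained_run]
        assert frames[0] == 0
        assert frames == sorted(frames)
        assert len(frames) >= 8
        assert all(np.isfinite(c.mean_eval_score) for c in trained_run)

    def test_recurrent_training_smoke(self):
        """The recurrent rung trains through BPTT without diverging."""
        qcfg = mini_config("recurrent")
        tcfg = TrainConfig(total_env_frames=3_000, checkpoint_every=10**9, seed=2,
                           update_every=8, min_replay=64, eval_episodes=2,
                           eval_max_frames=60)
        ckpts = train_agent(MiniCatch(seed=2), qcfg, tcfg,
                            eval_env_factory=lambda: MiniCatch(seed=3))
        assert all(np.all(np.isfinite(v)) for v in ckpts[-1].params.values())
        assert np.isfinite(ckpts[-1].mean_eval_score)


class TestEvaluateScore:
    def test_deterministic_given_seed(self, trained_checkpoint):
        a = evaluate_score(trained_checkpoint, MiniCatch(seed=4), n_episodes=5, seed=1)
        b = evaluate_score(trained_checkpoint, MiniCatch(seed=4), n_episodes=5, seed=1)
        assert a == b

    def test_random_policy_catch_rate_matches_brute_force(self):
        """Uniform-random play's per-drop catch rate agrees between two
        independent simulations (evaluation path vs a raw env rollout)."""
        ckpt = fresh_checkpoint("baseline", seed=50)
        # epsilon = 1 makes the checkpoint's play uniform random
        env = MiniCatch(seed=17)
        scores = [
            evaluate_score(ckpt, MiniCatch(seed=100 + i), n_episodes=10, epsilon=1.0,
                           seed=i, max_env_frames=600)
            for i in range(3)
        ]
        eval_catches = np.mean(scores)

        # brute-force rollout of the same stochastic policy
        rng = np.random.default_rng(0)
        env = MiniCatch(seed=55)
        env.reset()
        catches = drops = 0
        episodes = 0
        frames = 0
        total_catch = []
        ep_catch = 0.0
        while episodes < 200:
            _, r, term = env.step(int(rng.integers(3)))
            ep_catch += r
            frames += 1
            if term or frames >= 600:
                total_catch.append(ep_catch)
                ep_catch = 0.0
                frames = 0
                episodes += 1
                env.reset()
        brute = np.mean(total_catch)
        assert abs(eval_catches - brute) < 1.0  # same per-episode catch scale
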