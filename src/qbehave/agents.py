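"""Q-learning agents: the three-rung architecture ladder plus oracles.

The ladder mirrors the historical progression of deep Q-learning at toy
scale: a feed-forward baseline; a dueling head trained with double Q-learning
and n-step targets (the systems machinery of its distributed ancestor is
deliberately dropped); and a recurrent variant whose LSTM receives the last
reward, terminal flag and action vector as auxiliary inputs.

Training is classic DQN: epsilon-greedy interaction through a frame-skip
wrapper (action repeated over groups of 4 frames, observation = pixelwise max
of the last two frames of the group, matching the feature-extraction
preprocessing), uniform experience replay, Huber loss against bootstrap
targets, periodic target-network sync, optional reward clipping to [-1, 1].

A value-iteration oracle on explicit finite MDPs provides ground-truth Q*
for validating the learner.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .exceptions import DivergenceError, QBehaveError, ShapeMismatchError
from .network import Adam, QNetwork, QNetworkConfig, RecurrentState, mini_config
from .synthetic_data import EnvState


@dataclass
class TrainConfig:
    """Hyperparameters of the Q-learning loop.

    gamma/epsilon/batch_size/lr follow the classic DQN settings (0.99, 0.05,
    32, 2.5e-4); n_step > 1 and double Q-learning are the deltas of the
    dueling_double and recurrent rungs.
    """

    gamma: float = 0.99
    epsilon: float = 0.05
    batch_size: int = 32
    lr: float = 2.5e-4
    replay_capacity: int = 20_000
    target_sync_every: int = 200  # updates between target-net refreshes
    n_step: int = 1
    reward_clip: bool = True
    total_env_frames: int = 60_000
    checkpoint_every: int = 6_000  # in env frames
    seed: int = 0
    # implementation knobs
    double: bool | None = None  # default: True for non-baseline variants
    frame_skip: int = 4
    update_every: int = 1  # agent steps between gradient updates
    min_replay: int = 500  # transitions before learning starts (>= batch_size)
    seq_len: int = 8  # BPTT window for the recurrent variant
    max_episode_frames: int = 2_000  # truncate (not terminate) long training episodes
    eval_episodes: int = 50
    eval_max_frames: int = 240  # per-episode cap during evaluation

    def resolve_double(self, variant: str) -> bool:
        return self.double if self.double is not None else variant != "baseline"


@dataclass
class AgentCheckpoint:
    """Frozen weights + metadata; round-trips through save/load bit-exactly."""

    params: dict
    config: QNetworkConfig
    env_frames_seen: int
    mean_eval_score: float = float("nan")

    def to_network(self) -> QNetwork:
        net = QNetwork(self.config, seed=0)
        net.set_params(self.params)
        return net

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.params)
        manifest = {
            "config": asdict(self.config),
            "env_frames_seen": int(self.env_frames_seen),
            "mean_eval_score": float(self.mean_eval_score),
            "shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "AgentCheckpoint":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["conv_specs"] = tuple(tuple(s) for s in cfg_dict["conv_specs"])
        config = QNetworkConfig(**cfg_dict)
        with np.load(path.with_suffix(".npz")) as archive:
            params = {k: archive[k].copy() for k in archive.files}
        return cls(params, config, manifest["env_frames_seen"], manifest["mean_eval_score"])


# ---------------------------------------------------------------------------
# action selection and bootstrap targets


def epsilon_greedy(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Argmax with probability 1-epsilon (ties -> lowest index), else uniform."""
    q = np.asarray(q)
    if q.size == 0:
        raise QBehaveError("epsilon_greedy on an empty Q vector")
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(q.size))
    return int(np.argmax(q))


def td_target(reward, terminal, next_stack, gamma, double, online_net, target_net,
              discount=None):
    """Bootstrap target for one transition or a batch of them.

    terminal      -> reward
    vanilla       -> reward + gamma * max_a Q_target(next, a)
    double        -> reward + gamma * Q_target(next, argmax_a Q_online(next, a))

    `discount` overrides gamma**1 for n-step transitions (gamma**n).
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    reward = np.asarray(reward, dtype=np.float64)
    terminal = np.asarray(terminal, dtype=bool)
    q_t, _, _ = target_net.q_values(next_stack)
    q_t = np.atleast_2d(q_t)
    if double:
        q_o, _, _ = online_net.q_values(next_stack)
        best = np.argmax(np.atleast_2d(q_o), axis=1)
        bootstrap = q_t[np.arange(q_t.shape[0]), best]
    else:
        bootstrap = q_t.max(axis=1)
    disc = gamma if discount is None else np.asarray(discount, dtype=np.float64)
    out = reward + disc * bootstrap * (~terminal)
    return float(out[0]) if out.size == 1 and np.isscalar(reward.tolist()) else out


# ---------------------------------------------------------------------------
# environments seen by the trainer


class FrameSkipEnv:
    """Action repeat over `skip` frames; observation = max of the last two.

    This matches the video pipeline's pairwise-max downsampling, so agents
    train on the same observation statistics the feature extractor produces.
    """

    def __init__(self, env, skip: int = 4):
        self.env = env
        self.skip = skip
        self.n_actions = env.n_actions
        self.frame_shape = env.frame_shape

    def reset(self):
        frame = self.env.reset()
        return frame.astype(np.uint8)

    def step(self, action):
        total_reward = 0.0
        terminal = False
        frames = []
        for _ in range(self.skip):
            frame, reward, term = self.env.step(action)
            frames.append(frame)
            total_reward += reward
            terminal = terminal or term
            if term:
                break
        if len(frames) >= 2:
            obs = np.maximum(frames[-2], frames[-1])
        else:
            obs = frames[-1]
        return obs.astype(np.uint8), total_reward, terminal, len(frames)


class TabularMDPEnv:
    """Explicit finite MDP rendered as constant grayscale frames.

    State s is shown as a frame of intensity round(255 * s / (S-1)); the
    process is continuing (no terminals), which suits off-policy Q-learning.
    """

    def __init__(self, transitions: np.ndarray, rewards: np.ndarray, seed: int = 0,
                 frame_size: int = 4):
        self.P = np.asarray(transitions, dtype=np.float64)  # (S, A, S)
        self.R = np.asarray(rewards, dtype=np.float64)  # (S, A)
        self.n_states, self.n_actions = self.R.shape
        self.frame_size = frame_size
        self.frame_shape = (frame_size, frame_size)
        self.rng = np.random.default_rng(seed)
        self.state = 0

    def state_frame(self, s: int) -> np.ndarray:
        level = 255 if self.n_states == 1 else round(255 * s / (self.n_states - 1))
        return np.full(self.frame_shape, level, dtype=np.uint8)

    def reset(self):
        self.state = int(self.rng.integers(self.n_states))
        return self.state_frame(self.state)

    def step(self, action):
        reward = self.R[self.state, action]
        self.state = int(self.rng.choice(self.n_states, p=self.P[self.state, action]))
        return self.state_frame(self.state), float(reward), False


def analytic_two_action_mdp():
    """Single state, two self-loop actions with rewards 1 and 0.

    With gamma = 0.5 the optimal values are the geometric series
    Q*(a0) = 1/(1-0.5) = 2 and Q*(a1) = 0 + 0.5 * 2 = 1.
    """
    P = np.ones((1, 2, 1))
    R = np.array([[1.0, 0.0]])
    return P, R


def random_mdp(n_states: int, n_actions: int, seed: int = 0):
    """Random dense MDP with rewards in [0, 1)."""
    rng = np.random.default_rng(seed)
    P = rng.random((n_states, n_actions, n_states)) + 0.1
    P /= P.sum(axis=2, keepdims=True)
    R = rng.random((n_states, n_actions))
    return P, R


def value_iteration_oracle(transitions, rewards, gamma: float, tol: float = 1e-10,
                           max_iter: int = 100_000) -> np.ndarray:
    """Exact Q* by Bellman optimality iteration on an explicit finite MDP."""
    P = np.asarray(transitions, dtype=np.float64)
    R = np.asarray(rewards, dtype=np.float64)
    if not 0 <= gamma < 1:
        raise ValueError("value iteration requires 0 <= gamma < 1 (no contraction at 1)")
    q = np.zeros_like(R)
    for _ in range(max_iter):
        q_new = R + gamma * P @ q.max(axis=1)
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    raise QBehaveError("value iteration did not converge")


# ---------------------------------------------------------------------------
# replay buffers


class ReplayBuffer:
    """Uniform ring buffer of (stack, action, n-step reward, next stack, terminal)."""

    def __init__(self, capacity: int, stack_shape, rng: np.random.Generator):
        self.capacity = capacity
        self.rng = rng
        self.obs = np.empty((capacity, *stack_shape), dtype=np.uint8)
        self.next_obs = np.empty((capacity, *stack_shape), dtype=np.uint8)
        self.actions = np.empty(capacity, dtype=np.int64)
        self.rewards = np.empty(capacity, dtype=np.float64)
        self.terminals = np.empty(capacity, dtype=bool)
        self.idx = 0
        self.size = 0

    def push(self, obs, action, reward, next_obs, terminal):
        i = self.idx
        self.obs[i] = obs
        self.actions[i] = action
        self.rewards[i] = reward
        self.next_obs[i] = next_obs
        self.terminals[i] = terminal
        self.idx = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int):
        idx = self.rng.integers(self.size, size=batch_size)
        return (
            self.obs[idx].astype(np.float64) / 255.0,
            self.actions[idx],
            self.rewards[idx],
            self.next_obs[idx].astype(np.float64) / 255.0,
            self.terminals[idx],
        )


class EpisodeReplay:
    """Episode store for the recurrent variant; samples fixed-length windows."""

    def __init__(self, capacity_steps: int, seq_len: int, rng: np.random.Generator):
        self.capacity = capacity_steps
        self.seq_len = seq_len
        self.rng = rng
        self.episodes: deque = deque()
        self.total = 0

    def push_episode(self, episode: dict):
        n = len(episode["actions"])
        if n < self.seq_len + 1:
            return
        self.episodes.append(episode)
        self.total += n
        while self.total > self.capacity and len(self.episodes) > 1:
            self.total -= len(self.episodes[0]["actions"])
            self.episodes.popleft()

    @property
    def size(self) -> int:
        return self.total

    def sample(self, batch_size: int):
        """Batch of windows, each seq_len+1 observations long."""
        lengths = np.array([len(e["actions"]) for e in self.episodes])
        weights = lengths - self.seq_len
        weights = np.maximum(weights, 0)
        p = weights / weights.sum()
        out = []
        for _ in range(batch_size):
            e = self.episodes[int(self.rng.choice(len(self.episodes), p=p))]
            start = int(self.rng.integers(len(e["actions"]) - self.seq_len))
            out.append({k: v[start : start + self.seq_len + 1] for k, v in e.items()})
        return out


# ---------------------------------------------------------------------------
# training


def _huber_grad(td: np.ndarray) -> np.ndarray:
    # derivative of smooth-L1 with delta = 1
    return np.clip(td, -1.0, 1.0)


def _huber_loss(td: np.ndarray) -> float:
    a = np.abs(td)
    return float(np.mean(np.where(a <= 1.0, 0.5 * td**2, a - 0.5)))


class _FrameStacker:
    def __init__(self, depth: int):
        self.depth = depth
        self.frames: deque = deque(maxlen=depth)

    def reset(self, frame):
        self.frames.clear()
        for _ in range(self.depth):
            self.frames.append(frame)
        return self.stack()

    def push(self, frame):
        self.frames.append(frame)
        return self.stack()

    def stack(self):
        return np.stack(self.frames)


def _feedforward_update(net, target, opt, buffer, tcfg, disc):
    obs, actions, rewards, next_obs, terminals = buffer.sample(tcfg.batch_size)
    y = td_target(rewards, terminals, next_obs, tcfg.gamma,
                  tcfg.resolve_double(net.config.variant), net, target, discount=disc)
    q, _, cache = net.q_values(obs, keep_cache=True)
    rows = np.arange(tcfg.batch_size)
    td = q[rows, actions] - y
    loss = _huber_loss(td)
    if not np.isfinite(loss):
        raise DivergenceError(f"non-finite loss {loss}")
    dq = np.zeros_like(q)
    dq[rows, actions] = _huber_grad(td) / tcfg.batch_size
    grads, _ = net.backward(dq, cache)
    opt.step(net.params, grads)
    return loss


def _recurrent_update(net, target, opt, buffer, tcfg):
    windows = buffer.sample(tcfg.batch_size)
    L = tcfg.seq_len
    b = len(windows)
    obs = np.stack([w["obs"] for w in windows]).astype(np.float64) / 255.0  # (B, L+1, C, H, W)
    actions = np.stack([w["actions"] for w in windows])  # (B, L+1)
    rewards = np.stack([w["rewards"] for w in windows])
    terminals = np.stack([w["terminals"] for w in windows])
    aux = np.stack([w["aux"] for w in windows])  # (B, L+1, aux)

    double = tcfg.resolve_double("recurrent")

    # online pass with caches
    state = RecurrentState.zeros(net.config, b)
    t_state = RecurrentState.zeros(net.config, b)
    o_state2 = RecurrentState.zeros(net.config, b)
    qs, caches = [], []
    q_next_t, q_next_o = [], []
    for t in range(L + 1):
        state.aux = aux[:, t]
        q, state, cache = net.q_values(obs[:, t], state, keep_cache=True)
        qs.append(q)
        caches.append(cache)
        t_state.aux = aux[:, t]
        qt, t_state, _ = target.q_values(obs[:, t], t_state)
        q_next_t.append(qt)
        if double:
            o_state2.aux = aux[:, t]
            qo, o_state2, _ = net.q_values(obs[:, t], o_state2)
            q_next_o.append(qo)

    rows = np.arange(b)
    dqs = []
    total_loss = 0.0
    mask_alive = np.ones(b, dtype=bool)
    for t in range(L):
        sel = q_next_o[t + 1].argmax(axis=1) if double else q_next_t[t + 1].argmax(axis=1)
        bootstrap = q_next_t[t + 1][rows, sel]
        y = rewards[:, t] + tcfg.gamma * bootstrap * (~terminals[:, t])
        td = (qs[t][rows, actions[:, t]] - y) * mask_alive
        total_loss += _huber_loss(td)
        dq = np.zeros_like(qs[t])
        dq[rows, actions[:, t]] = _huber_grad(td) / (b * L)
        dqs.append(dq)
        mask_alive = mask_alive & ~terminals[:, t]
    dqs.append(np.zeros_like(qs[0]))

    if not np.isfinite(total_loss):
        raise DivergenceError(f"non-finite loss {total_loss}")

    grads: dict = {}
    drec = None
    for t in reversed(range(L + 1)):
        grads, drec = net.backward(dqs[t], caches[t], grads=grads, drec=drec)
    opt.step(net.params, grads)
    return total_loss / L


def train_agent(env, qcfg: QNetworkConfig, tcfg: TrainConfig, eval_env_factory=None):
    """Train one agent and return its checkpoint trajectory.

    `env` must expose reset()/step(action)/n_actions/frame_shape.  Checkpoints
    are emitted at env-frame 0, every `checkpoint_every` env frames, and at
    the end; `mean_eval_score` is filled by :func:`evaluate_score` using
    `eval_env_factory` (a zero-argument callable returning a fresh env;
    defaults to reusing `env`'s class via `env_factory` attribute if absent
    the scores stay NaN unless a factory is given).
    """
    rng = np.random.default_rng(tcfg.seed)
    net = QNetwork(qcfg, seed=int(rng.integers(2**31)))
    target = net.copy()
    opt = Adam(net.params, lr=tcfg.lr)
    recurrent = qcfg.variant == "recurrent"

    wrapped = FrameSkipEnv(env, tcfg.frame_skip)
    stacker = _FrameStacker(qcfg.input_frames)
    stack_shape = (qcfg.input_frames, *wrapped.frame_shape)
    if wrapped.frame_shape != (qcfg.input_size, qcfg.input_size):
        raise ShapeMismatchError(
            f"env frames {wrapped.frame_shape} do not match network input "
            f"{qcfg.input_size}x{qcfg.input_size}"
        )

    if recurrent:
        buffer = EpisodeReplay(tcfg.replay_capacity, tcfg.seq_len, rng)
    else:
        buffer = ReplayBuffer(tcfg.replay_capacity, stack_shape, rng)
    min_replay = max(tcfg.batch_size, tcfg.min_replay)

    checkpoints = [AgentCheckpoint({k: v.copy() for k, v in net.params.items()}, qcfg, 0)]
    next_ckpt = tcfg.checkpoint_every

    # --- episode state
    obs = wrapped.reset()
    stack = stacker.reset(obs)
    rec_state = RecurrentState.zeros(qcfg, 1) if recurrent else None
    episode = _new_episode(stack, qcfg) if recurrent else None
    pending: deque = deque()  # (stack, action, reward, next_stack, terminal) pre n-step

    env_frames = 0
    updates = 0
    agent_steps = 0
    episode_frames = 0

    while env_frames < tcfg.total_env_frames:
        if recurrent:
            q, rec_state, _ = net.q_values(stack.astype(np.float64) / 255.0, rec_state)
        else:
            q, _, _ = net.q_values(stack.astype(np.float64) / 255.0)
        action = epsilon_greedy(np.ravel(q), tcfg.epsilon, rng)

        obs, reward, terminal, used = wrapped.step(action)
        env_frames += used
        episode_frames += used
        truncate = not terminal and episode_frames >= tcfg.max_episode_frames
        clipped = float(np.clip(reward, -1.0, 1.0)) if tcfg.reward_clip else float(reward)
        next_stack = stacker.push(obs)

        if recurrent:
            _append_step(episode, action, clipped, terminal, next_stack, qcfg)
            new_aux = np.zeros((1, qcfg.aux_size))
            new_aux[0, 0] = clipped
            new_aux[0, 1] = float(terminal)
            new_aux[0, 2 + action] = 1.0
            rec_state.aux = new_aux
        else:
            pending.append([stack, action, [clipped]])
            if len(pending) > tcfg.n_step:
                raise AssertionError("n-step queue overflow")
            for item in list(pending)[:-1]:
                item[2].append(clipped)
            if len(pending) == tcfg.n_step or terminal:
                while pending:
                    s0, a0, rs = pending.popleft()
                    ret = sum((tcfg.gamma**i) * r for i, r in enumerate(rs))
                    buffer.push(s0, a0, ret, next_stack, terminal)
                    if not terminal:
                        break

        stack = next_stack
        agent_steps += 1

        if buffer.size >= min_replay and agent_steps % tcfg.update_every == 0:
            if recurrent:
                _recurrent_update(net, target, opt, buffer, tcfg)
            else:
                disc = tcfg.gamma**tcfg.n_step
                _feedforward_update(net, target, opt, buffer, tcfg, disc)
            updates += 1
            if updates % tcfg.target_sync_every == 0:
                target.set_params(net.params)

        if terminal or truncate:
            if recurrent:
                buffer.push_episode(_finish_episode(episode, terminal=terminal))
            obs = wrapped.reset()
            stack = stacker.reset(obs)
            pending.clear()
            episode_frames = 0
            if recurrent:
                rec_state = RecurrentState.zeros(qcfg, 1)
                episode = _new_episode(stack, qcfg)

        if env_frames >= next_ckpt:
            checkpoints.append(
                AgentCheckpoint({k: v.copy() for k, v in net.params.items()}, qcfg, env_frames)
            )
            next_ckpt += tcfg.checkpoint_every

    if checkpoints[-1].env_frames_seen < env_frames:
        checkpoints.append(
            AgentCheckpoint({k: v.copy() for k, v in net.params.items()}, qcfg, env_frames)
        )

    if eval_env_factory is not None:
        # one shared seed so every checkpoint faces the same evaluation bank
        for ckpt in checkpoints:
            ckpt.mean_eval_score = evaluate_score(
                ckpt, eval_env_factory(), n_episodes=tcfg.eval_episodes,
                epsilon=tcfg.epsilon, seed=tcfg.seed + 7919,
                frame_skip=tcfg.frame_skip, max_env_frames=tcfg.eval_max_frames,
            )
    return checkpoints


def _new_episode(stack, qcfg):
    return {
        "obs": [stack.copy()],
        "actions": [],
        "rewards": [],
        "terminals": [],
        "aux": [np.zeros(qcfg.aux_size)],
    }


def _append_step(episode, action, reward, terminal, next_stack, qcfg):
    episode["obs"].append(next_stack.copy())
    episode["actions"].append(action)
    episode["rewards"].append(reward)
    episode["terminals"].append(terminal)
    aux = np.zeros(qcfg.aux_size)
    aux[0] = reward
    aux[1] = float(terminal)
    aux[2 + action] = 1.0
    episode["aux"].append(aux)


def _finish_episode(episode, terminal=True):
    # a trailing dummy step so every real step has a successor observation
    return {
        "obs": np.stack(episode["obs"]),
        "actions": np.array(episode["actions"] + [0]),
        "rewards": np.array(episode["rewards"] + [0.0]),
        "terminals": np.array(episode["terminals"] + [terminal]),
        "aux": np.stack(episode["aux"]),
    }


def random_checkpoint(qcfg: QNetworkConfig, seed: int) -> AgentCheckpoint:
    """A frames-0 checkpoint with freshly initialized weights."""
    net = QNetwork(qcfg, seed=seed)
    return AgentCheckpoint({k: v.copy() for k, v in net.params.items()}, qcfg, 0)


def tabular_q_learning_error(transitions, rewards, gamma: float = 0.5,
                             total_env_frames: int = 25_000, seed: int = 7,
                             lr: float = 1e-3, epsilon: float = 0.5) -> float:
    """Sup-norm distance between network Q-learning and the exact oracle.

    Trains the mini network on the rendered MDP (single-frame input so the
    state is fully observed) and reads out Q(s, a) for every state.
    """
    q_star = value_iteration_oracle(transitions, rewards, gamma)
    env = TabularMDPEnv(transitions, rewards, seed=1, frame_size=4)
    qcfg = mini_config("baseline", n_actions=env.n_actions, input_size=4, input_frames=1)
    tcfg = TrainConfig(gamma=gamma, epsilon=epsilon, total_env_frames=total_env_frames,
                       checkpoint_every=10**9, frame_skip=1, reward_clip=False,
                       lr=lr, target_sync_every=100, min_replay=200,
                       max_episode_frames=500, seed=seed)
    net = train_agent(env, qcfg, tcfg)[-1].to_network()
    learned = np.array([
        np.ravel(net.q_values(env.state_frame(s)[None].astype(np.float64) / 255.0)[0])
        for s in range(env.n_states)
    ])
    return float(np.max(np.abs(learned - q_star)))


def evaluate_score(checkpoint: AgentCheckpoint, env, n_episodes: int = 50,
                   epsilon: float = 0.05, seed: int = 0, frame_skip: int = 4,
                   max_env_frames: int = 240) -> float:
    """Mean episode score under epsilon-greedy play; seeded and reproducible.

    Episodes are capped at `max_env_frames` environment frames so evaluation
    time stays bounded even for strong agents on non-terminating tasks.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    net = checkpoint.to_network()
    qcfg = checkpoint.config
    rng = np.random.default_rng(seed)
    wrapped = FrameSkipEnv(env, frame_skip)
    stacker = _FrameStacker(qcfg.input_frames)
    recurrent = qcfg.variant == "recurrent"

    scores = []
    for _ in range(n_episodes):
        obs = wrapped.reset()
        stack = stacker.reset(obs)
        rec_state = RecurrentState.zeros(qcfg, 1) if recurrent else None
        total = 0.0
        frames = 0
        while frames < max_env_frames:
            x = stack.astype(np.float64) / 255.0
            if recurrent:
                q, rec_state, _ = net.q_values(x, rec_state)
            else:
                q, _, _ = net.q_values(x)
            action = epsilon_greedy(np.ravel(q), epsilon, rng)
            obs, reward, terminal, used = wrapped.step(action)
            frames += used
            total += reward
            stack = stacker.push(obs)
            if recurrent:
                aux = np.zeros((1, qcfg.aux_size))
                aux[0, 0] = float(np.clip(reward, -1, 1))
                aux[0, 1] = float(terminal)
                aux[0, 2 + action] = 1.0
                rec_state.aux = aux
            if terminal:
                break
        scores.append(total)
    return float(np.mean(scores))


class AgentPolicy:
    """Adapter that lets a checkpoint play through :func:`simulate_session`.

    Re-implements the frame-skip preprocessing incrementally: every
    `frame_skip` base frames the pixelwise max of the last two frames enters
    the FIFO stack and a fresh action is chosen; in between, the action is
    repeated.
    """

    def __init__(self, checkpoint: AgentCheckpoint, epsilon: float = 0.05, seed: int = 0,
                 frame_skip: int = 4):
        self.net = checkpoint.to_network()
        self.qcfg = checkpoint.config
        self.epsilon = epsilon
        self.rng = np.random.default_rng(seed)
        self.frame_skip = frame_skip
        self.recurrent = self.qcfg.variant == "recurrent"
        self._reset()

    def _reset(self):
        self._stacker = _FrameStacker(self.qcfg.input_frames)
        self._stack = None
        self._recent: deque = deque(maxlen=2)
        self._t = 0
        self._action = 0
        self._rec_state = RecurrentState.zeros(self.qcfg, 1) if self.recurrent else None
        self._acc_reward = 0.0

    def __call__(self, state: EnvState, frame: np.ndarray, last_reward: float = 0.0,
                 last_terminal: bool = False) -> int:
        if last_terminal:
            self._reset()
        self._recent.append(frame)
        self._acc_reward += last_reward
        if self._t % self.frame_skip == 0:
            obs = np.maximum(*self._recent) if len(self._recent) == 2 else frame
            if self._stack is None:
                self._stack = self._stacker.reset(obs)
            else:
                self._stack = self._stacker.push(obs)
            x = self._stack.astype(np.float64) / 255.0
            if self.recurrent:
                q, self._rec_state, _ = self.net.q_values(x, self._rec_state)
                aux = np.zeros((1, self.qcfg.aux_size))
                aux[0, 0] = float(np.clip(self._acc_reward, -1, 1))
                aux[0, 2 + self._action] = 1.0
                self._rec_state.aux = aux
            else:
                q, _, _ = self.net.q_values(x)
            self._action = epsilon_greedy(np.ravel(q), self.epsilon, self.rng)
            self._acc_reward = 0.0
        self._t += 1
        return self._action
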