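"""Synthetic game sessions and synthetic responders.

MiniCatch is a deliberately small paddle-and-ball game: a ball drops from the
top of a grid one row per frame, the player slides a paddle along the bottom
row, a catch scores a point and a miss costs a life.  Its state space is tiny
enough that the induced MDP can be solved exactly, while its rendered frames
still exercise the full video pipeline (grayscale screens, episodes inside
sessions, rewards, terminals).

Synthetic responders replace human key-press logs: at every time step an
action is sampled from a softmax over the (z-scored) Q-values, with an
additive preference for the no-op, a hold probability that reproduces the
autocorrelation of real key presses, and a motor lag that delays the emitted
indicator series.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import UnknownActionError

ACTIONS = ("noop", "left", "right")
NOOP, LEFT, RIGHT = 0, 1, 2

BASE_RATE_HZ = 45.0
DEFAULT_SESSION_FRAMES = 20_000

BACKGROUND_VALUE = 0
PADDLE_VALUE = 128
BALL_VALUE = 255


@dataclass
class EnvConfig:
    """Geometry and rules of MiniCatch."""

    width: int = 12
    height: int = 12
    paddle_width: int = 3
    lives_max: int = 3


@dataclass
class EnvState:
    """Full game state; `rng` is the opaque seedable state used for respawns."""

    paddle_x: int
    ball_x: int
    ball_y: int
    lives: int
    score: int
    rng: np.random.Generator

    def copy(self) -> "EnvState":
        return replace(self, rng=copy.deepcopy(self.rng))


@dataclass
class SessionRecord:
    """One simulated session: frames plus per-frame action/reward/terminal logs."""

    frames: np.ndarray  # (n, H, W) uint8
    actions: np.ndarray  # (n, n_actions) 0/1 indicator
    rewards: np.ndarray  # (n,) float
    terminals: np.ndarray  # (n,) bool
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ResponderConfig:
    """Stochastic policy emulating a human responder.

    beta       softmax inverse temperature on z-scored Q-values (unitless).
    lag        motor delay, in frames of the series the responder is applied to.
    noop_bias  additive logit preference for the no-op entry.
    hold_prob  probability of repeating the previous action instead of resampling,
               producing key-press autocorrelation.
    """

    beta: float = 2.0
    lag: int = 4
    noop_bias: float = 0.5
    hold_prob: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if not 0 <= self.hold_prob < 1:
            raise ValueError(f"hold_prob must be in [0, 1), got {self.hold_prob}")


def initial_state(cfg: EnvConfig, seed: int) -> EnvState:
    rng = np.random.default_rng(seed)
    return EnvState(
        paddle_x=(cfg.width - cfg.paddle_width) // 2,
        ball_x=int(rng.integers(cfg.width)),
        ball_y=0,
        lives=cfg.lives_max,
        score=0,
        rng=rng,
    )


def render_frame(state: EnvState, cfg: EnvConfig) -> np.ndarray:
    frame = np.full((cfg.height, cfg.width), BACKGROUND_VALUE, dtype=np.uint8)
    frame[cfg.height - 1, state.paddle_x : state.paddle_x + cfg.paddle_width] = PADDLE_VALUE
    frame[state.ball_y, state.ball_x] = BALL_VALUE
    return frame


def step_env(state: EnvState, action: int, cfg: EnvConfig = EnvConfig()):
    """Advance MiniCatch by one frame.

    Returns (new_state, frame, reward, terminal).  The paddle moves first
    (clipped at the walls), then the ball descends one row; when it reaches
    the bottom row the catch/miss is resolved and the ball respawns at a
    seeded-random top column.
    """
    if action not in (NOOP, LEFT, RIGHT):
        raise UnknownActionError(f"unknown action id {action!r}; expected 0..2 {ACTIONS}")

    s = state.copy()
    if action == LEFT:
        s.paddle_x = max(0, s.paddle_x - 1)
    elif action == RIGHT:
        s.paddle_x = min(cfg.width - cfg.paddle_width, s.paddle_x + 1)

    reward = 0.0
    terminal = False
    s.ball_y += 1
    if s.ball_y >= cfg.height - 1:
        caught = s.paddle_x <= s.ball_x < s.paddle_x + cfg.paddle_width
        if caught:
            reward = 1.0
            s.score += 1
        else:
            s.lives -= 1
            terminal = s.lives <= 0
        s.ball_y = 0
        s.ball_x = int(s.rng.integers(cfg.width))

    return s, render_frame(s, cfg), reward, terminal


class MiniCatch:
    """Stateful wrapper around :func:`step_env` with gym-like reset/step."""

    def __init__(self, cfg: EnvConfig | None = None, seed: int = 0):
        self.cfg = cfg or EnvConfig()
        self._seed = seed
        self._episode = 0
        self.state: EnvState | None = None

    @property
    def n_actions(self) -> int:
        return len(ACTIONS)

    @property
    def frame_shape(self):
        return (self.cfg.height, self.cfg.width)

    def reset(self) -> np.ndarray:
        # each episode draws a fresh stream so resets never replay respawns
        self.state = initial_state(self.cfg, (self._seed, self._episode))
        self._episode += 1
        return render_frame(self.state, self.cfg)

    def step(self, action: int):
        self.state, frame, reward, terminal = step_env(self.state, action, self.cfg)
        return frame, reward, terminal


# ---------------------------------------------------------------------------
# policies


def random_policy(seed: int = 0):
    """Uniform-random action each frame."""
    rng = np.random.default_rng(seed)

    def policy(state: EnvState, frame: np.ndarray, *feedback) -> int:
        return int(rng.integers(len(ACTIONS)))

    return policy


def toward_ball_policy(epsilon: float = 0.0, seed: int = 0):
    """Move the paddle center toward the ball column; optional random slips."""
    rng = np.random.default_rng(seed)

    def policy(state: EnvState, frame: np.ndarray, *feedback) -> int:
        if epsilon > 0 and rng.random() < epsilon:
            return int(rng.integers(len(ACTIONS)))
        center = state.paddle_x + 1  # paddle_width // 2 for the default width 3
        if state.ball_x < center:
            return LEFT
        if state.ball_x > center:
            return RIGHT
        return NOOP

    return policy


def simulate_session(
    policy,
    n_frames: int = DEFAULT_SESSION_FRAMES,
    seed: int = 0,
    cfg: EnvConfig | None = None,
    game: str = "minicatch",
) -> SessionRecord:
    """Play `policy` for exactly `n_frames` frames, restarting episodes on terminal.

    `policy` is called as ``policy(state, frame, last_reward, last_terminal)
    -> action_id`` before every frame (the feedback arguments let agent
    policies thread recurrent state).  Identical (policy, n_frames, seed)
    yield a bit-identical record.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cfg = cfg or EnvConfig()
    env = MiniCatch(cfg, seed=seed)
    frame = env.reset()

    frames = np.empty((n_frames, cfg.height, cfg.width), dtype=np.uint8)
    actions = np.zeros((n_frames, len(ACTIONS)), dtype=np.uint8)
    rewards = np.zeros(n_frames, dtype=np.float64)
    terminals = np.zeros(n_frames, dtype=bool)

    last_reward, last_terminal = 0.0, False
    for t in range(n_frames):
        action = policy(env.state, frame, last_reward, last_terminal)
        frame, reward, terminal = env.step(action)
        last_reward, last_terminal = reward, terminal
        frames[t] = frame
        actions[t, action] = 1
        rewards[t] = reward
        terminals[t] = terminal
        if terminal:
            frame = env.reset()

    meta = {"game": game, "seed": seed, "n_frames": n_frames, "rate_hz": BASE_RATE_HZ}
    return SessionRecord(frames, actions, rewards, terminals, meta)


# ---------------------------------------------------------------------------
# synthetic responder


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(values, dtype=np.float64)
    np.divide(values - mean, sd, out=out, where=sd > 0)
    return out


def generate_responses(
    q_values: np.ndarray,
    cfg: ResponderConfig,
    noop_index: int = NOOP,
) -> np.ndarray:
    """Sample a binary response train from a Q-value time series.

    At each step an action is drawn from ``softmax(beta * z(Q) + noop_bias)``
    (z-scoring across actions makes beta scale-free); with probability
    `hold_prob` the previous action is repeated instead.  The emitted one-hot
    series is then delayed by `lag` frames, zeros filling the gap (a causal
    motor delay).  Exactly one action is sampled per step before the shift.
    """
    cfg.validate()
    q = np.asarray(q_values, dtype=np.float64)
    if q.ndim != 2 or q.shape[1] < 2:
        raise ValueError("q_values must be (time, actions) with >= 2 actions")
    if not np.all(np.isfinite(q)):
        raise ValueError("q_values must be finite")

    n, a = q.shape
    logits = cfg.beta * _zscore_rows(q)
    logits[:, noop_index] += cfg.noop_bias
    # stable softmax
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(cfg.seed)
    u = rng.random(n)
    hold = rng.random(n) < cfg.hold_prob
    cum = np.cumsum(probs, axis=1)
    sampled = (u[:, None] >= cum).sum(axis=1)  # inverse-CDF draw per row

    chosen = np.empty(n, dtype=np.int64)
    prev = noop_index
    for t in range(n):
        prev = prev if hold[t] else int(sampled[t])
        chosen[t] = prev

    onehot = np.zeros((n, a), dtype=np.uint8)
    onehot[np.arange(n), chosen] = 1

    if cfg.lag > 0:
        shifted = np.zeros_like(onehot)
        if cfg.lag < n:
            shifted[cfg.lag :] = onehot[: n - cfg.lag]
        return shifted
    return onehot
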