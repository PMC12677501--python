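"""Video preprocessing and Q-series extraction.

A recorded session (grayscale frames at 45 Hz) becomes the encoding model's
predictor matrix in four deterministic steps: pairwise-max temporal
downsampling to 11.25 Hz, spatial resize to the network's input resolution,
FIFO stacking to depth 4, and a forward pass of a frozen checkpoint per
stack.  Recurrent checkpoints thread their hidden state across the whole
session (reward and terminal flags as auxiliary inputs, the action vector
fixed to zeros so the agent's own choices cannot leak into the features);
``ablate_memory=True`` zeroes the hidden state before every step, which makes
the evaluation exactly stateless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _skimage_resize

from .agents import AgentCheckpoint
from .exceptions import ShapeMismatchError
from .network import RecurrentState
from .synthetic_data import ACTIONS, SessionRecord

DOWNSAMPLE_FACTOR = 4


@dataclass
class QSeries:
    """Time-by-action Q-value matrix at the feature rate (base rate / 4)."""

    values: np.ndarray  # (T, n_actions) float64
    action_labels: tuple = ACTIONS
    rate_hz: float = 11.25
    source: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


def pairwise_max_downsample(frames: np.ndarray) -> np.ndarray:
    """Elementwise max over the third and fourth frame of each group of four.

    Input at the base rate, output at base/4; a trailing partial group is
    dropped.  Works on (n, ...) arrays of any frame shape, including scalars.
    """
    frames = np.asarray(frames)
    n = frames.shape[0]
    if n < DOWNSAMPLE_FACTOR:
        raise ValueError(f"need at least {DOWNSAMPLE_FACTOR} frames, got {n}")
    k = n // DOWNSAMPLE_FACTOR
    groups = frames[: k * DOWNSAMPLE_FACTOR].reshape(k, DOWNSAMPLE_FACTOR, *frames.shape[1:])
    return np.maximum(groups[:, 2], groups[:, 3])


def downsample_rewards(rewards: np.ndarray) -> np.ndarray:
    """Per-group reward sums at the feature rate (companion to the frame path)."""
    rewards = np.asarray(rewards, dtype=np.float64)
    k = rewards.shape[0] // DOWNSAMPLE_FACTOR
    return rewards[: k * DOWNSAMPLE_FACTOR].reshape(k, DOWNSAMPLE_FACTOR).sum(axis=1)


def downsample_terminals(terminals: np.ndarray) -> np.ndarray:
    terminals = np.asarray(terminals, dtype=bool)
    k = terminals.shape[0] // DOWNSAMPLE_FACTOR
    return terminals[: k * DOWNSAMPLE_FACTOR].reshape(k, DOWNSAMPLE_FACTOR).any(axis=1)


def resize_frame(frame: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to target_size x target_size, clipped to [0, 255]."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape == (target_size, target_size):
        return frame
    out = _skimage_resize(
        frame, (target_size, target_size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 255.0)


def stack_frames(frames: np.ndarray, depth: int = 4) -> np.ndarray:
    """FIFO stacks: stack t = frames[t-depth+1 .. t], head padded by repetition.

    Returns (n, depth, H, W); exactly one stack per input frame.
    """
    frames = np.asarray(frames)
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    n = frames.shape[0]
    idx = np.arange(n)[:, None] + np.arange(-depth + 1, 1)[None, :]
    idx = np.maximum(idx, 0)
    return frames[idx]


def extract_q_series(
    checkpoint: AgentCheckpoint,
    session: SessionRecord,
    ablate_memory: bool = False,
    batch_size: int = 512,
) -> QSeries:
    """Run a session's video through a frozen checkpoint.

    Deterministic given (checkpoint, session).  Feed-forward variants are
    evaluated in batches; recurrent variants sequentially, threading the
    hidden state (or zeroing it each step when `ablate_memory`).
    """
    qcfg = checkpoint.config
    net = checkpoint.to_network()

    down = pairwise_max_downsample(session.frames)
    if down.shape[1:] != (qcfg.input_size, qcfg.input_size):
        down = np.stack([resize_frame(f, qcfg.input_size) for f in down])
    else:
        down = down.astype(np.float64)
    stacks = stack_frames(down, qcfg.input_frames) / 255.0
    n = stacks.shape[0]

    if qcfg.variant != "recurrent":
        chunks = []
        for start in range(0, n, batch_size):
            q, _, _ = net.q_values(stacks[start : start + batch_size])
            chunks.append(np.atleast_2d(q))
        values = np.concatenate(chunks, axis=0)
    else:
        rewards = np.clip(downsample_rewards(session.rewards), -1.0, 1.0)
        terminals = downsample_terminals(session.terminals)
        state = RecurrentState.zeros(qcfg, 1)
        values = np.empty((n, qcfg.n_actions))
        for t in range(n):
            if ablate_memory:
                state = RecurrentState.zeros(qcfg, 1)
            aux = np.zeros((1, qcfg.aux_size))
            if t > 0:
                aux[0, 0] = rewards[t - 1]
                aux[0, 1] = float(terminals[t - 1])
            # action entries stay zero during feature generation
            state.aux = aux
            q, state, _ = net.q_values(stacks[t : t + 1], state)
            values[t] = q[0]

    if not np.all(np.isfinite(values)):
        raise ShapeMismatchError("non-finite Q-values extracted")
    rate = session.meta.get("rate_hz", 45.0) / DOWNSAMPLE_FACTOR
    source = {
        "checkpoint_frames": checkpoint.env_frames_seen,
        "variant": qcfg.variant,
        "session_seed": session.meta.get("seed"),
        "ablate_memory": ablate_memory,
    }
    return QSeries(values=values, action_labels=ACTIONS[: qcfg.n_actions], rate_hz=rate,
                   source=source)
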