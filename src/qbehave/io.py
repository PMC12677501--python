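"""On-disk formats: TSV time series with JSON sidecars, binary array containers.

Sessions store their frames in a .npy container with a JSON sidecar (dtype,
shape, rate, seed) and their per-frame logs as TSV with columns
``t, action_<label>..., reward, terminal``; Q-series are TSV with a JSON
sidecar carrying rate and provenance.  Checkpoints are handled by
:meth:`qbehave.agents.AgentCheckpoint.save`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import QSeries
from .synthetic_data import ACTIONS, SessionRecord


def save_session(session: SessionRecord, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "frames.npy", session.frames)
    sidecar = {
        "dtype": str(session.frames.dtype),
        "shape": list(session.frames.shape),
        "hz": session.meta.get("rate_hz", 45.0),
        "seed": session.meta.get("seed"),
        "game": session.meta.get("game", "minicatch"),
    }
    (directory / "frames.json").write_text(json.dumps(sidecar, indent=2))

    n_actions = session.actions.shape[1]
    df = pd.DataFrame({"t": np.arange(session.n_frames)})
    for i in range(n_actions):
        df[f"action_{ACTIONS[i]}"] = session.actions[:, i]
    df["reward"] = session.rewards
    df["terminal"] = session.terminals.astype(int)
    df.to_csv(directory / "log.tsv", sep="\t", index=False)
    return directory


def load_session(directory) -> SessionRecord:
    directory = Path(directory)
    frames = np.load(directory / "frames.npy")
    sidecar = json.loads((directory / "frames.json").read_text())
    df = pd.read_csv(directory / "log.tsv", sep="\t")
    action_cols = [c for c in df.columns if c.startswith("action_")]
    return SessionRecord(
        frames=frames,
        actions=df[action_cols].to_numpy(dtype=np.uint8),
        rewards=df["reward"].to_numpy(dtype=np.float64),
        terminals=df["terminal"].to_numpy(dtype=bool),
        meta={"game": sidecar.get("game"), "seed": sidecar.get("seed"),
              "n_frames": frames.shape[0], "rate_hz": sidecar.get("hz", 45.0)},
    )


def save_qseries(q: QSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": np.arange(q.n_steps)})
    for i, label in enumerate(q.action_labels):
        df[f"q_{label}"] = q.values[:, i]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"rate_hz": q.rate_hz, "action_labels": list(q.action_labels),
               "source": q.source}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_qseries(path) -> QSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    labels = sidecar["action_labels"]
    values = df[[f"q_{a}" for a in labels]].to_numpy(dtype=np.float64)
    return QSeries(values=values, action_labels=tuple(labels),
                   rate_hz=sidecar["rate_hz"], source=sidecar.get("source", {}))


def save_responses(responses: np.ndarray, path, action_labels=ACTIONS) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": np.arange(len(responses))})
    for i, label in enumerate(action_labels[: responses.shape[1]]):
        df[f"action_{label}"] = responses[:, i]
    df.to_csv(path, sep="\t", index=False)
    return path
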