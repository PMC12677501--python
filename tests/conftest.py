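import numpy as np
import pytest

from qbehave.agents import AgentCheckpoint, TrainConfig, train_agent
from qbehave.network import QNetwork, mini_config
from qbehave.synthetic_data import MiniCatch


def fresh_checkpoint(variant: str, seed: int, **kwargs) -> AgentCheckpoint:
    """A randomly initialized (frames-0) checkpoint of the given variant."""
    cfg = mini_config(variant, **kwargs)
    net = QNetwork(cfg, seed=seed)
    return AgentCheckpoint({k: v.copy() for k, v in net.params.items()}, cfg, 0)


@pytest.fixture(scope="session")
def trained_run():
    """One MiniCatch training run of the dueling+double rung, with eval scores.

    Shared across the suite: the learning-curve, end-to-end recovery and
    smoothing-sweep checks all consume its checkpoints.
    """
    qcfg = mini_config("dueling_double")
    tcfg = TrainConfig(total_env_frames=60_000, checkpoint_every=6_000, seed=11,
                       n_step=3, update_every=4)
    return train_agent(MiniCatch(seed=11), qcfg, tcfg,
                       eval_env_factory=lambda: MiniCatch(seed=99))


@pytest.fixture(scope="session")
def trained_checkpoint(trained_run):
    return trained_run[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
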