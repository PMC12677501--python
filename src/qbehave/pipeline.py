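"""End-to-end study harness.

A synthetic "subject" is a bank of recorded sessions plus a responder: the
sessions provide video, a frozen checkpoint turns the video into Q-value
features, the responder samples a key-press train from those features, and
the encoding stage fits and cross-validates the per-action logistic models.
The helpers here wire those stages together with one seed per study so that
tests, analyses and the acceptance script all run the identical pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import AgentCheckpoint
from .analysis import apply_lag, phase_shuffle
from .encoding import (
    EncodedSession,
    align_series,
    build_design,
    crossval_predict,
    make_kernel,
    smooth,
    upsample_q,
    zscore_across_actions,
)
from .features import QSeries, extract_q_series
from .synthetic_data import (
    BASE_RATE_HZ,
    ResponderConfig,
    SessionRecord,
    simulate_session,
    toward_ball_policy,
)

DEFAULT_N_SESSIONS = 7
DEFAULT_SESSION_FRAMES = 2_000  # toy-scale session length (the full design is 20,000)


def simulate_study(seed: int, n_sessions: int = DEFAULT_N_SESSIONS,
                   session_frames: int = DEFAULT_SESSION_FRAMES,
                   policy_epsilon: float = 0.25) -> list[SessionRecord]:
    """A bank of sessions of near-competent scripted play with random slips."""
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_sessions):
        s = int(rng.integers(2**31))
        policy = toward_ball_policy(epsilon=policy_epsilon, seed=s)
        sessions.append(simulate_session(policy, n_frames=session_frames, seed=s))
    return sessions


def study_features(checkpoint: AgentCheckpoint, sessions, ablate_memory: bool = False):
    return [extract_q_series(checkpoint, s, ablate_memory=ablate_memory) for s in sessions]


def study_responses(q_list, cfg: ResponderConfig, upsample_factor: int = 4):
    """Responder key logs at the base rate, one independent seed per session."""
    responses = []
    for i, q in enumerate(q_list):
        session_cfg = ResponderConfig(beta=cfg.beta, lag=cfg.lag, noop_bias=cfg.noop_bias,
                                      hold_prob=cfg.hold_prob, seed=cfg.seed + 10_007 * i)
        from .synthetic_data import generate_responses

        q_up = upsample_q(q.values, upsample_factor)
        responses.append(generate_responses(q_up, session_cfg))
    return responses


def encode_study(q_list, response_list, fwhm_seconds: float = 0.79,
                 target_mode: str = "smoothed", shift_lag: int = 0,
                 intercept_column: str = "noop", ridge: float = 1e-4,
                 target_actions=None, rate_hz: float = BASE_RATE_HZ,
                 upsample_factor: int = 4):
    """Run the full encoding pipeline on one subject's sessions.

    Per session: upsample the Q-series to the base rate, z-score across
    actions, align predictors and responses (asymmetric head/tail trims),
    optionally shift the responses by `shift_lag` extra frames, smooth both
    with the same Gaussian kernel, replace the intercept column, then
    cross-validate one logistic model per target action across sessions.

    Returns (fold_df, mean_r) where mean_r averages folds first, then
    actions.
    """
    if len(q_list) != len(response_list):
        raise ValueError("need one response series per Q-series")
    labels = tuple(q_list[0].action_labels)
    if target_actions is None:
        target_actions = tuple(a for a in labels if a != intercept_column)
    kernel = make_kernel(fwhm_seconds, rate_hz)

    prepared = []  # per session: (q_smoothed, resp_smoothed, resp_raw)
    for q, resp in zip(q_list, response_list):
        values = q.values if isinstance(q, QSeries) else np.asarray(q)
        q_up = zscore_across_actions(upsample_q(values, upsample_factor))
        q_al, r_al = align_series(q_up, resp)
        if shift_lag != 0:
            q_al, r_al = apply_lag(q_al, r_al, shift_lag)
        q_s = smooth(q_al, kernel)
        r_s = smooth(r_al.astype(np.float64), kernel)
        prepared.append((q_s, r_s, r_al))

    k = len(prepared)
    frames = []
    for action in target_actions:
        a_idx = labels.index(action)
        sessions = [
            EncodedSession(
                design=build_design(q_s, labels, intercept_column),
                target_smoothed=r_s[:, a_idx],
                target_raw=r_raw[:, a_idx].astype(np.float64),
                session_id=i,
            )
            for i, (q_s, r_s, r_raw) in enumerate(prepared)
        ]
        folds = crossval_predict(sessions, k=k, target_mode=target_mode,
                                 ridge=ridge, action=action)
        frames.extend(
            {"action": f.action, "fold": f.held_out_session, "r": f.pearson_r,
             "excluded": f.excluded, "target_mode": f.target_mode}
            for f in folds
        )
    df = pd.DataFrame.from_records(frames)
    valid = df[~df["excluded"]]
    mean_r = float(valid.groupby("action")["r"].mean().mean()) if len(valid) else float("nan")
    return df, mean_r


def action_usage(response_list) -> dict:
    """Fraction of sessions in which each action column is pressed at least once."""
    from .synthetic_data import ACTIONS

    counts = np.zeros(response_list[0].shape[1])
    for resp in response_list:
        counts += (np.asarray(resp).sum(axis=0) > 0)
    return {a: counts[i] / len(response_list) for i, a in enumerate(ACTIONS[: counts.size])}


def subject_table(fold_df: pd.DataFrame, variant: str, subject: int,
                  game: str = "minicatch") -> pd.DataFrame:
    """Fold results -> the row format the aggregation stage expects."""
    df = fold_df.copy()
    df["variant"] = variant
    df["subject"] = subject
    df["game"] = game
    return df


def history_dependence_study(seed: int, n_sessions: int = DEFAULT_N_SESSIONS,
                             session_frames: int = DEFAULT_SESSION_FRAMES,
                             responder_cfg: ResponderConfig | None = None):
    """Recurrent vs feed-forward features on a history-dependent responder.

    The responder is driven by a recurrent network's memoryful Q-series, so
    its policy depends on frames far beyond the 4-frame stack; the same
    responses are then fit once with the recurrent features and once with a
    matched feed-forward baseline's features.  Returns (r_recurrent,
    r_baseline).
    """
    from .agents import random_checkpoint
    from .network import mini_config

    rec = random_checkpoint(mini_config("recurrent"), seed=100_003 + seed)
    base = random_checkpoint(mini_config("baseline"), seed=200_003 + seed)
    cfg = responder_cfg or ResponderConfig(beta=2.0, lag=4, seed=seed)

    sessions = simulate_study(seed, n_sessions, session_frames)
    q_rec = study_features(rec, sessions)
    responses = study_responses(q_rec, cfg)
    _, r_rec = encode_study(q_rec, responses)
    q_base = study_features(base, sessions)
    _, r_base = encode_study(q_base, responses)
    return r_rec, r_base


def end_to_end_recovery(checkpoint: AgentCheckpoint, seed: int,
                        responder_cfg: ResponderConfig | None = None,
                        n_sessions: int = DEFAULT_N_SESSIONS,
                        session_frames: int = DEFAULT_SESSION_FRAMES,
                        fwhm_seconds: float = 0.79,
                        target_mode: str = "smoothed"):
    """Matched vs phase-shuffled cross-validated accuracy for one subject.

    Responses are sampled from the checkpoint's own Q-series; the control
    re-runs the identical pipeline on phase-randomized surrogates of every
    Q predictor, which preserves each predictor's power spectrum but destroys
    its temporal alignment with the responses.
    """
    cfg = responder_cfg or ResponderConfig(beta=2.0, lag=0, noop_bias=0.0,
                                           hold_prob=0.0, seed=seed)
    sessions = simulate_study(seed, n_sessions, session_frames)
    q_list = study_features(checkpoint, sessions)
    responses = study_responses(q_list, cfg)
    _, r_matched = encode_study(q_list, responses, fwhm_seconds=fwhm_seconds,
                                target_mode=target_mode)

    rng = np.random.default_rng(seed + 555_557)
    q_shuffled = [
        QSeries(values=phase_shuffle(q.values, rng), action_labels=q.action_labels,
                rate_hz=q.rate_hz, source={**q.source, "surrogate": "phase_shuffle"})
        for q in q_list
    ]
    _, r_control = encode_study(q_shuffled, responses, fwhm_seconds=fwhm_seconds,
                                target_mode=target_mode)
    return r_matched, r_control
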