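"""Logistic encoding models on Q-value features.

The per-action encoding model is a logistic GLM: z-scored (across actions)
and Gaussian-smoothed Q-value time series predict a binary (or smoothed,
fractional) response train.  One predictor column is replaced by a constant 1
to act as the baseline; fits are scored by the Pearson correlation between
the predicted probability series and the held-out session's response series
under 7-fold leave-one-session-out cross-validation.

Smoothing uses the discrete convolution

    (u * g)_k = sum_{j = max(1, k+1-n)}^{min(k, m)} u_j g_{k-j+1},
    k in [1, n+m-1]

of a series u (length m) with a normalized Gaussian kernel g (length n); the
full-length result is center-cropped back to length m so predictors and
targets stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConvergenceError,
    DegenerateTargetError,
    QBehaveError,
    UnknownActionError,
)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

# the asymmetric head/tail trims that align feature-rate-derived predictors
# with base-rate responses (a built-in 4-frame response shift)
Q_TRIM_HEAD = 12
Q_TRIM_TAIL = 3
RESP_TRIM_HEAD = 16


@dataclass
class SmoothingKernel:
    """Truncated, normalized Gaussian kernel on integer sample offsets."""

    sigma_samples: float
    fwhm_seconds: float
    rate_hz: float
    radius: int
    weights: np.ndarray

    def __len__(self) -> int:
        return self.weights.size


@dataclass
class DesignMatrix:
    """Predictor matrix with exactly one constant (baseline) column."""

    matrix: np.ndarray  # (T, P)
    columns: tuple
    intercept_index: int

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FoldResult:
    held_out_session: int
    action: str
    coefficients: np.ndarray
    pearson_r: float
    target_mode: str
    excluded: bool = False


@dataclass
class EncodedSession:
    """One session's per-action regression inputs, preprocessed identically."""

    design: DesignMatrix
    target_smoothed: np.ndarray
    target_raw: np.ndarray
    session_id: int = 0


@dataclass
class AccuracyTable:
    """Fold-level correlations plus the fold->action->subject aggregates."""

    rows: pd.DataFrame  # variant, subject, game, action, fold, r (+ optional checkpoint)
    per_subject: pd.DataFrame
    aggregates: pd.DataFrame


# ---------------------------------------------------------------------------
# series preprocessing


def upsample_q(values: np.ndarray, factor: int = 4) -> np.ndarray:
    """Repeat each feature-rate row `factor` times (11.25 Hz -> 45 Hz)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.asarray(values), factor, axis=0)


def zscore_across_actions(q: np.ndarray) -> np.ndarray:
    """Per-time-step z-score across the action axis (sample sd, n-1).

    Constant rows map to all zeros, which keeps early near-constant
    checkpoints usable.
    """
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if q.shape[1] < 2:
        raise ValueError("need at least 2 actions to standardize across")
    mean = q.mean(axis=1, keepdims=True)
    sd = q.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(q)
    np.divide(q - mean, sd, out=out, where=sd > 0)
    return out


def binarize_responses(labels, action_labels) -> np.ndarray:
    """Key log -> 0/1 indicator matrix, one column per elementary action.

    Combined labels such as ``"fire-right"`` set both columns at that frame.
    """
    index = {a: i for i, a in enumerate(action_labels)}
    out = np.zeros((len(labels), len(action_labels)), dtype=np.uint8)
    for t, label in enumerate(labels):
        for part in str(label).split("-"):
            if part not in index:
                raise UnknownActionError(f"unknown action label {part!r} at frame {t}")
            out[t, index[part]] = 1
    return out


def align_series(q_up: np.ndarray, responses: np.ndarray):
    """Trim both base-rate series onto the common analysis window.

    Drops the first 12 and last 3 rows of the (upsampled) Q series and the
    first 16 rows of the responses, then truncates both to the shorter
    length.  The asymmetric trims shift the responses 4 frames earlier
    relative to the predictors, absorbing a short motor delay.
    """
    q_up = np.asarray(q_up)
    responses = np.asarray(responses)
    if q_up.shape[0] <= Q_TRIM_HEAD + Q_TRIM_TAIL or responses.shape[0] <= RESP_TRIM_HEAD:
        raise ValueError(
            f"series too short for the trims: Q has {q_up.shape[0]} rows, "
            f"responses {responses.shape[0]}"
        )
    q_t = q_up[Q_TRIM_HEAD : q_up.shape[0] - Q_TRIM_TAIL]
    r_t = responses[RESP_TRIM_HEAD:]
    n = min(q_t.shape[0], r_t.shape[0])
    return q_t[:n], r_t[:n]


# ---------------------------------------------------------------------------
# smoothing


def make_kernel(fwhm_seconds: float, rate_hz: float, radius_sigmas: float = 4.0) -> SmoothingKernel:
    """Normalized Gaussian kernel; sigma (in samples) = FWHM * rate / 2.3548.

    The kernel is truncated at +-radius_sigmas * sigma and renormalized to
    sum 1; a sub-sample sigma collapses to the identity kernel [1].
    """
    if fwhm_seconds <= 0:
        raise ValueError("fwhm_seconds must be > 0")
    sigma = fwhm_seconds * rate_hz / FWHM_PER_SIGMA
    radius = int(round(radius_sigmas * sigma))
    if radius < 1 or sigma < 1e-12:
        weights = np.array([1.0])
        radius = 0
    else:
        offsets = np.arange(-radius, radius + 1, dtype=np.float64)
        weights = np.exp(-0.5 * (offsets / sigma) ** 2)
        weights /= weights.sum()
    return SmoothingKernel(sigma, fwhm_seconds, rate_hz, radius, weights)


def full_convolve(u: np.ndarray, g: np.ndarray) -> np.ndarray:
    """The full-length (m+n-1) discrete convolution of the smoothing formula."""
    u = np.asarray(u, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if u.size < 1 or g.size < 1:
        raise ValueError("series and kernel must be non-empty")
    return np.convolve(u, g, mode="full")


def smooth(series: np.ndarray, kernel: SmoothingKernel | np.ndarray) -> np.ndarray:
    """Convolve columnwise and center-crop back to the input length."""
    g = kernel.weights if isinstance(kernel, SmoothingKernel) else np.asarray(kernel, float)
    series = np.asarray(series, dtype=np.float64)
    n = g.size
    head = (n - 1) // 2
    if series.ndim == 1:
        return full_convolve(series, g)[head : head + series.shape[0]]
    out = np.empty_like(series)
    for j in range(series.shape[1]):
        out[:, j] = full_convolve(series[:, j], g)[head : head + series.shape[0]]
    return out


# ---------------------------------------------------------------------------
# design + GLM


def build_design(q_smoothed: np.ndarray, columns, intercept_column: str = "noop") -> DesignMatrix:
    """Replace one predictor column with a constant 1 baseline."""
    columns = tuple(columns)
    if intercept_column not in columns:
        raise UnknownActionError(f"no column {intercept_column!r} in {columns}")
    idx = columns.index(intercept_column)
    mat = np.array(q_smoothed, dtype=np.float64, copy=True)
    mat[:, idx] = 1.0
    return DesignMatrix(mat, columns, idx)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def fit_action_glm(design: DesignMatrix, target: np.ndarray, ridge: float = 1e-4,
                   max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Penalized logistic fit by Newton iteration.

    Maximizes the Bernoulli log-likelihood (valid for fractional targets in
    [0, 1]) minus an L2 penalty `ridge` on all coefficients except the one on
    the constant baseline column.
    """
    x = design.matrix
    y = np.asarray(target, dtype=np.float64)
    if y.shape[0] != x.shape[0]:
        raise ValueError("design and target lengths differ")
    if np.min(y) < -1e-9 or np.max(y) > 1 + 1e-9:
        raise ValueError("target values must lie in [0, 1]")
    if np.ptp(y) == 0:
        raise DegenerateTargetError("target series is constant")

    p = x.shape[1]
    penalty = np.full(p, ridge)
    penalty[design.intercept_index] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = _sigmoid(eta)
        grad = x.T @ (y - mu) - penalty * beta
        w = np.maximum(mu * (1 - mu), 1e-10)
        hess = (x * w[:, None]).T @ x + np.diag(np.maximum(penalty, 1e-12))
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise ConvergenceError(
        "logistic fit did not converge",
        diagnostics={"max_step": float(np.max(np.abs(step))), "iterations": max_iter},
    )


def predict_glm(design: DesignMatrix, beta: np.ndarray) -> np.ndarray:
    return _sigmoid(design.matrix @ beta)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def crossval_predict(sessions, k: int = 7, target_mode: str = "smoothed",
                     ridge: float = 1e-4, action: str = "") -> list[FoldResult]:
    """Leave-one-session-out cross-validation for one action's GLM.

    Fits on the concatenated smoothed targets of the k-1 training sessions,
    predicts logistic probabilities on the held-out design, and scores
    Pearson r against the held-out smoothed (``target_mode='smoothed'``) or
    raw binary (``'unsmoothed'``) series.  Folds with a degenerate held-out
    or training target are flagged `excluded` and skipped in aggregation.
    """
    if target_mode not in ("smoothed", "unsmoothed"):
        raise ValueError("target_mode must be 'smoothed' or 'unsmoothed'")
    if len(sessions) != k:
        raise ValueError(f"expected {k} sessions, got {len(sessions)}")

    results = []
    for i, held in enumerate(sessions):
        train = [s for j, s in enumerate(sessions) if j != i]
        x_train = np.vstack([s.design.matrix for s in train])
        y_train = np.concatenate([s.target_smoothed for s in train])
        design_train = DesignMatrix(x_train, held.design.columns, held.design.intercept_index)
        try:
            beta = fit_action_glm(design_train, y_train, ridge=ridge)
        except DegenerateTargetError:
            results.append(FoldResult(held.session_id, action, np.full(x_train.shape[1], np.nan),
                                      float("nan"), target_mode, excluded=True))
            continue
        pred = predict_glm(held.design, beta)
        target = held.target_smoothed if target_mode == "smoothed" else held.target_raw
        r = _pearson(pred, target)
        results.append(FoldResult(held.session_id, action, beta, r, target_mode,
                                  excluded=not np.isfinite(r)))
    return results


# ---------------------------------------------------------------------------
# aggregation


def aggregate(rows: pd.DataFrame, min_sessions_with_action: float = 0.0,
              last_k_checkpoints: int | None = None,
              action_usage: dict | None = None) -> AccuracyTable:
    """Fold -> action -> subject means, with rare-action exclusion.

    `rows` needs columns (variant, subject, game, action, fold, r) and may
    carry `excluded` and `checkpoint` (env frames) columns.  `action_usage`
    maps action label -> fraction of sessions in which the action occurs;
    actions below `min_sessions_with_action` are dropped.  When
    `last_k_checkpoints` is given, only the k highest-frame checkpoints per
    variant enter the aggregate.
    """
    if len(rows) == 0:
        raise QBehaveError("no fold results to aggregate")
    df = rows.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df[np.isfinite(df["r"])]

    if min_sessions_with_action > 0:
        if action_usage is None:
            raise QBehaveError("min_sessions_with_action > 0 requires action_usage")
        keep = [a for a in df["action"].unique()
                if action_usage.get(a, 0.0) >= min_sessions_with_action]
        df = df[df["action"].isin(keep)]
    if len(df) == 0:
        raise QBehaveError("all actions excluded from aggregation")

    if last_k_checkpoints is not None and "checkpoint" in df.columns:
        def _keep_last(group):
            last = sorted(group["checkpoint"].unique())[-last_k_checkpoints:]
            return group[group["checkpoint"].isin(last)]
        df = df.groupby("variant", group_keys=False)[df.columns].apply(_keep_last)

    keys = ["variant", "subject", "game"]
    per_action = df.groupby(keys + ["action"], as_index=False)["r"].mean()
    per_subject = per_action.groupby(keys, as_index=False)["r"].mean()
    aggregates = per_subject.groupby(["variant", "game"], as_index=False)["r"].mean()
    return AccuracyTable(rows=rows, per_subject=per_subject, aggregates=aggregates)
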