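"""Result surfaces and statistics.

Three analyses sit on top of the encoding pipeline: the architecture-ladder
comparison (Fisher-z transforms, one-sample t-tests against chance,
repeated-measures ANOVA with Greenhouse-Geisser correction, Bonferroni post
hocs), the smoothing-kernel sweep (prediction accuracy as a function of the
Gaussian FWHM, against smoothed and raw targets), and the training-checkpoint
curve (evaluation score vs prediction accuracy across a training run).  An
FFT amplitude spectrum and a response-lag shift supply the supporting
diagnostics, and phase-randomized surrogates provide the chance control for
end-to-end recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateStatisticError, QBehaveError


@dataclass
class StatReport:
    per_variant: dict  # variant -> {mean_r, mean_z, t, df, p, cohens_d}
    anova: dict  # {F, df1, df2, gg_epsilon, p_gg}
    pairwise: dict  # (variant_a, variant_b) -> {t, p_adjusted}


@dataclass
class SweepResult:
    fwhm_grid: np.ndarray
    mean_r_smoothed: np.ndarray
    mean_r_unsmoothed: np.ndarray
    per_seed: pd.DataFrame  # seed, fwhm, target_mode, r


@dataclass
class CheckpointCurve:
    env_frames: np.ndarray
    mean_eval_score: np.ndarray
    mean_r: np.ndarray
    r_dqn: float  # Pearson between score and accuracy curves
    degenerate: bool = False


# ---------------------------------------------------------------------------
# elementary statistics


def fisher_z(r):
    """Fisher's z-transform, atanh(r); odd and strictly increasing on (-1, 1)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise DegenerateStatisticError("|r| >= 1 has no finite Fisher z")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def one_sample_t(values, mu0: float = 0.0):
    """Two-sided one-sample t-test; returns (t, df, p, cohens_d)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise DegenerateStatisticError("one-sample t needs n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError("one-sample t undefined for zero variance")
    res = stats.ttest_1samp(values, mu0)
    d = float((values.mean() - mu0) / sd)
    return float(res.statistic), int(values.size - 1), float(res.pvalue), d


def _check_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DegenerateStatisticError("need a complete (subjects >= 2) x (conditions >= 2) matrix")
    if not np.all(np.isfinite(m)):
        raise DegenerateStatisticError("incomplete matrix (non-finite entries)")
    return m


def rm_anova(matrix):
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Returns (F, df1, df2, gg_epsilon, p_gg).  The Greenhouse-Geisser epsilon
    comes from the double-centered condition covariance; with two conditions
    it is exactly 1 and F equals the squared paired-t statistic.
    """
    m = _check_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)

    tiny = 1e-12 * (ss_total + 1e-300)  # guard against pure rounding residue
    if ss_cond <= tiny:
        f_stat = 0.0
    elif ss_err <= tiny:
        raise DegenerateStatisticError("zero within-subject error variance")
    else:
        f_stat = (ss_cond / df1) / (ss_err / df2)

    # Greenhouse-Geisser epsilon from the double-centered covariance
    s = np.cov(m, rowvar=False, ddof=1)
    centered = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * np.sum(centered**2)
    eps = 1.0 if denom <= 1e-300 else float(np.trace(centered) ** 2 / denom)
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    p_gg = float(stats.f.sf(f_stat, eps * df1, eps * df2)) if f_stat > 0 else 1.0
    return float(f_stat), df1, df2, eps, p_gg


def pairwise_t_bonferroni(matrix, labels=None):
    """Paired t-tests on every condition pair, Bonferroni-adjusted.

    p_adjusted = min(1, n_pairs * p_raw).  An identical pair returns (0, 1);
    a constant nonzero difference (zero-variance paired sd) is rejected.
    """
    m = _check_matrix(matrix)
    k = m.shape[1]
    labels = list(labels) if labels is not None else list(range(k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    n_pairs = len(pairs)
    out = {}
    for i, j in pairs:
        diff = m[:, i] - m[:, j]
        if np.all(diff == 0):
            t_stat, p_adj = 0.0, 1.0
        elif diff.std(ddof=1) <= 1e-12 * (np.abs(diff).max() + 1e-300):
            raise DegenerateStatisticError(
                f"degenerate paired sd for pair ({labels[i]}, {labels[j]})"
            )
        else:
            res = stats.ttest_rel(m[:, i], m[:, j])
            t_stat = float(res.statistic)
            p_adj = min(1.0, n_pairs * float(res.pvalue))
        out[(labels[i], labels[j])] = {"t": t_stat, "p_adjusted": p_adj}
    return out


def compare_variants(per_subject_r: dict) -> StatReport:
    """Architecture-ladder comparison on per-subject mean correlations.

    `per_subject_r` maps variant -> array of per-subject mean r (same
    subjects, same order, under every variant).  Correlations are Fisher-z
    transformed; chance is z = 0.
    """
    variants = list(per_subject_r)
    mat_r = np.column_stack([np.asarray(per_subject_r[v], dtype=np.float64) for v in variants])
    mat_z = np.arctanh(mat_r)

    per_variant = {}
    for i, v in enumerate(variants):
        z = mat_z[:, i]
        t_stat, df, p, d = one_sample_t(z, 0.0)
        per_variant[v] = {
            "mean_r": float(mat_r[:, i].mean()),
            "mean_z": float(z.mean()),
            "t": t_stat, "df": df, "p": p, "cohens_d": d,
        }

    if len(variants) >= 2:
        f_stat, df1, df2, eps, p_gg = rm_anova(mat_z)
        anova = {"F": f_stat, "df1": df1, "df2": df2, "gg_epsilon": eps, "p_gg": p_gg}
        pairwise = pairwise_t_bonferroni(mat_z, labels=variants)
    else:  # a single variant leaves nothing to compare
        anova, pairwise = {}, {}
    return StatReport(per_variant, anova, pairwise)


# ---------------------------------------------------------------------------
# signal diagnostics


def fft_spectrum(series, rate_hz: float):
    """One-sided, energy-normalized amplitude spectrum (DC included).

    Amplitudes are scaled so that sum(amplitude**2) equals sum(series**2)
    (Parseval); the frequency axis runs from 0 to the Nyquist rate.
    """
    u = np.asarray(series, dtype=np.float64)
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    n = u.size
    x = np.fft.rfft(u)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    weights = np.full(x.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    amps = np.abs(x) * np.sqrt(weights / n)
    return freqs, amps


def shift_series(responses: np.ndarray, lag_frames: int) -> np.ndarray:
    """Advance (lag > 0) or delay (lag < 0) a response series by whole frames.

    A positive lag compensates a motor delay by moving responses earlier;
    the result is |lag| frames shorter and the paired predictor series must
    be truncated from the matching end (see :func:`apply_lag`).
    """
    responses = np.asarray(responses)
    n = responses.shape[0]
    if abs(lag_frames) >= n:
        raise ValueError(f"|lag| = {abs(lag_frames)} must be < series length {n}")
    if lag_frames == 0:
        return responses
    if lag_frames > 0:
        return responses[lag_frames:]
    return responses[:n + lag_frames]


def apply_lag(predictors: np.ndarray, responses: np.ndarray, lag_frames: int):
    """Shift responses by `lag_frames` and truncate the predictors to match."""
    shifted = shift_series(responses, lag_frames)
    n = shifted.shape[0]
    if lag_frames >= 0:
        return predictors[:n], shifted
    return predictors[-n:], shifted


def phase_shuffle(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate, columnwise: same power spectrum, scrambled timing."""
    v = np.atleast_2d(np.asarray(values, dtype=np.float64).T).T
    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        x = np.fft.rfft(v[:, j])
        phases = rng.uniform(0, 2 * np.pi, x.size)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = rng.choice([0.0, np.pi])
        out[:, j] = np.fft.irfft(np.abs(x) * np.exp(1j * phases), n)
    return out.reshape(np.shape(values))


# ---------------------------------------------------------------------------
# experiment surfaces


def smoothing_sweep(study_factory, fwhm_grid, seeds, encode_kwargs=None) -> SweepResult:
    """Prediction accuracy across a FWHM grid, for both target modes.

    `study_factory(seed)` must return (q_series_list, response_list) for one
    synthetic subject; the encoding pipeline is run per grid value and seed
    with the smoothed and the raw target.
    """
    from .pipeline import encode_study

    fwhm_grid = np.asarray(sorted(fwhm_grid), dtype=np.float64)
    if fwhm_grid.size == 0:
        raise ValueError("fwhm_grid must be non-empty")
    encode_kwargs = dict(encode_kwargs or {})
    records = []
    for seed in seeds:
        q_list, resp_list = study_factory(int(seed))
        for fwhm in fwhm_grid:
            for mode in ("smoothed", "unsmoothed"):
                _, mean_r = encode_study(q_list, resp_list, fwhm_seconds=float(fwhm),
                                         target_mode=mode, **encode_kwargs)
                records.append({"seed": int(seed), "fwhm": float(fwhm),
                                "target_mode": mode, "r": mean_r})
    df = pd.DataFrame.from_records(records)
    means = df.groupby(["target_mode", "fwhm"])["r"].mean()
    return SweepResult(
        fwhm_grid=fwhm_grid,
        mean_r_smoothed=means.loc["smoothed"].reindex(fwhm_grid).to_numpy(),
        mean_r_unsmoothed=means.loc["unsmoothed"].reindex(fwhm_grid).to_numpy(),
        per_seed=df,
    )


def checkpoint_curve(checkpoints, sessions, responder_cfg, drive_checkpoint=None,
                     eval_env_factory=None, eval_kwargs=None,
                     encode_kwargs=None) -> CheckpointCurve:
    """Evaluation score vs prediction accuracy across a training trajectory.

    Responses are generated once from `drive_checkpoint` (default: the
    final checkpoint) and held fixed; every checkpoint is then scored on the
    same responder data.  The summary r_DQN is the Pearson correlation
    between the raw score curve and the raw accuracy curve; it is flagged
    degenerate when either curve has zero variance.
    """
    from .agents import evaluate_score
    from .pipeline import encode_study, study_features, study_responses

    if len(checkpoints) < 3:
        raise QBehaveError("need at least 3 checkpoints")
    encode_kwargs = dict(encode_kwargs or {})
    drive = drive_checkpoint or checkpoints[-1]
    drive_q = study_features(drive, sessions)
    responses = study_responses(drive_q, responder_cfg)

    frames, scores, accs = [], [], []
    for ckpt in checkpoints:
        score = ckpt.mean_eval_score
        if not np.isfinite(score):
            if eval_env_factory is None:
                raise QBehaveError("checkpoint lacks a score and no eval env was given")
            score = evaluate_score(ckpt, eval_env_factory(), **(eval_kwargs or {}))
        q_list = study_features(ckpt, sessions)
        _, mean_r = encode_study(q_list, responses, **encode_kwargs)
        frames.append(ckpt.env_frames_seen)
        scores.append(score)
        accs.append(mean_r)

    scores = np.asarray(scores)
    accs = np.asarray(accs)
    degenerate = scores.std() == 0 or accs.std() == 0
    r_dqn = float("nan") if degenerate else float(np.corrcoef(scores, accs)[0, 1])
    return CheckpointCurve(np.asarray(frames), scores, accs, r_dqn, degenerate)
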