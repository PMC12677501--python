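import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qbehave.encoding import (
    DesignMatrix,
    EncodedSession,
    aggregate,
    align_series,
    binarize_responses,
    build_design,
    crossval_predict,
    fit_action_glm,
    full_convolve,
    make_kernel,
    smooth,
    upsample_q,
    zscore_across_actions,
)
from qbehave.exceptions import (
    DegenerateTargetError,
    QBehaveError,
    UnknownActionError,
)


def brute_force_convolution(u, g):
    """Direct double-loop evaluation of the convolution sum (1-based formula)."""
    m, n = len(u), len(g)
    out = np.zeros(m + n - 1)
    for k in range(1, m + n):
        lo = max(1, k + 1 - n)
        hi = min(k, m)
        out[k - 1] = sum(u[j - 1] * g[k - j] for j in range(lo, hi + 1))
    return out


class TestPreprocessing:
    def test_upsample_repeats_rows_in_order(self):
        out = upsample_q(np.array([[1.0, 2.0], [3.0, 4.0]]), 4)
        assert out.tolist() == [[1, 2]] * 4 + [[3, 4]] * 4

    def test_upsample_restores_base_length(self, rng):
        assert upsample_q(rng.random((5_000, 3))).shape == (20_000, 3)

    def test_upsample_factor_one_is_identity(self, rng):
        q = rng.random((7, 3))
        assert np.array_equal(upsample_q(q, 1), q)

    def test_zscore_unit_rows_unchanged(self):
        assert np.allclose(zscore_across_actions([[-1.0, 0.0, 1.0]]), [[-1, 0, 1]])

    def test_zscore_constant_row_maps_to_zeros(self):
        assert np.array_equal(zscore_across_actions([[2.0, 2.0, 2.0]]), [[0, 0, 0]])

    def test_zscore_two_actions_sample_sd(self):
        out = zscore_across_actions([[0.0, 2.0]])
        assert np.allclose(out, [[-0.70711, 0.70711]], atol=1e-5)

    def test_binarize_splits_combined_actions(self):
        labels = ("fire", "left", "right", "noop")
        out = binarize_responses(["fire-right", "noop", "left"], labels)
        assert out[0].tolist() == [1, 0, 1, 0]
        assert out[1].tolist() == [0, 0, 0, 1]
        assert out[2].tolist() == [0, 1, 0, 0]

    def test_binarize_column_sums_conserve_presses(self):
        labels = ("fire", "left", "noop")
        log = ["fire", "fire-left", "noop", "left", "fire"]
        out = binarize_responses(log, labels)
        assert out.sum(axis=0).tolist() == [3, 2, 1]

    def test_binarize_unknown_label_rejected(self):
        with pytest.raises(UnknownActionError):
            binarize_responses(["jump"], ("noop",))

    def test_align_trims_full_session(self, rng):
        q, r = align_series(rng.random((20_000, 3)), rng.random((20_000, 3)))
        assert q.shape[0] == r.shape[0] == 19_984

    def test_align_trims_short_series(self, rng):
        q, r = align_series(rng.random((20, 3)), rng.random((20, 3)))
        assert q.shape[0] == r.shape[0] == 4

    def test_align_rejects_too_short(self, rng):
        with pytest.raises(ValueError):
            align_series(rng.random((15, 3)), rng.random((15, 3)))


class TestKernel:
    def test_sigma_from_fwhm_at_base_rate(self):
        k = make_kernel(0.79, 45.0)
        assert k.sigma_samples == pytest.approx(15.097, abs=1e-3)

    def test_weights_normalized_and_symmetric(self):
        k = make_kernel(1.57, 45.0)
        assert k.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k.weights, k.weights[::-1])

    def test_tiny_fwhm_collapses_to_delta(self):
        k = make_kernel(1e-4, 45.0)
        assert k.weights.tolist() == [1.0]

    def test_fwhm_sigma_identity(self):
        k = make_kernel(0.5, 30.0)
        assert k.fwhm_seconds == pytest.approx(
            k.sigma_samples * 2 * np.sqrt(2 * np.log(2)) / k.rate_hz)


class TestSmooth:
    def test_hand_expanded_convolution(self):
        assert full_convolve([1, 0, 0], [0.5, 0.5]).tolist() == [0.5, 0.5, 0.0, 0.0]

    def test_delta_kernel_is_identity(self, rng):
        u = rng.random(50)
        assert np.array_equal(smooth(u, np.array([1.0])), u)

    def test_normalized_kernel_conserves_sum(self, rng):
        u = rng.random(200)
        g = make_kernel(0.5, 45.0).weights
        assert full_convolve(u, g).sum() == pytest.approx(u.sum(), abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(1, 40), st.integers(1, 15), st.integers(0, 10_000))
    def test_matches_brute_force_double_loop(self, m, n, seed):
        rng = np.random.default_rng(seed)
        u, g = rng.normal(size=m), rng.normal(size=n)
        assert np.max(np.abs(full_convolve(u, g) - brute_force_convolution(u, g))) <= 1e-12

    def test_center_crop_preserves_length_columnwise(self, rng):
        series = rng.random((100, 3))
        out = smooth(series, make_kernel(0.79, 45.0))
        assert out.shape == series.shape


class TestDesignAndGLM:
    def test_build_design_replaces_one_column(self, rng):
        q = rng.random((10, 4))
        d = build_design(q, ("noop", "a", "b", "c"), "noop")
        assert np.all(d.matrix[:, 0] == 1.0)
        assert np.array_equal(d.matrix[:, 1:], q[:, 1:])
        assert d.matrix[:, 0].var() == 0

    def test_build_design_alternative_intercept(self, rng):
        q = rng.random((10, 3))
        d = build_design(q, ("noop", "left", "right"), "left")
        assert d.intercept_index == 1
        assert np.array_equal(d.matrix[:, 0], q[:, 0])

    def test_missing_intercept_label_rejected(self, rng):
        with pytest.raises(UnknownActionError):
            build_design(rng.random((5, 2)), ("a", "b"), "noop")

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(123)
        x = np.column_stack([rng.standard_normal((5_000, 3)), np.ones(5_000)])
        truth = np.array([1.5, -0.8, 0.3, -1.0])
        y = (rng.random(5_000) < 1 / (1 + np.exp(-x @ truth))).astype(float)
        d = DesignMatrix(x, ("x1", "x2", "x3", "const"), 3)
        beta = fit_action_glm(d, y, ridge=1e-4)
        assert np.all(np.abs(beta - truth) < 0.15)

    def test_permuted_predictor_coefficient_near_zero(self):
        rng = np.random.default_rng(123)
        x = np.column_stack([rng.standard_normal((5_000, 3)), np.ones(5_000)])
        truth = np.array([1.5, -0.8, 0.3, -1.0])
        y = (rng.random(5_000) < 1 / (1 + np.exp(-x @ truth))).astype(float)
        x_perm = x.copy()
        x_perm[:, 0] = rng.permutation(x_perm[:, 0])
        beta = fit_action_glm(DesignMatrix(x_perm, ("x1", "x2", "x3", "const"), 3), y)
        assert abs(beta[0]) < 0.1

    def test_fractional_targets_accepted(self, rng):
        x = np.column_stack([rng.standard_normal(500), np.ones(500)])
        y = 1 / (1 + np.exp(-(0.8 * x[:, 0] - 0.2)))
        beta = fit_action_glm(DesignMatrix(x, ("x", "const"), 1), y, ridge=1e-6)
        assert np.allclose(beta, [0.8, -0.2], atol=1e-3)

    def test_constant_target_is_degenerate(self, rng):
        x = np.column_stack([rng.standard_normal(50), np.ones(50)])
        with pytest.raises(DegenerateTargetError):
            fit_action_glm(DesignMatrix(x, ("x", "const"), 1), np.zeros(50))

    def test_agrees_with_statsmodels_binomial_glm(self, rng):
        """Independent library route: unpenalized statsmodels GLM on the same data."""
        sm = pytest.importorskip("statsmodels.api")
        x = np.column_stack([rng.standard_normal((2_000, 2)), np.ones(2_000)])
        y = (rng.random(2_000) < 1 / (1 + np.exp(-(x @ [0.7, -0.4, 0.1])))).astype(float)
        mine = fit_action_glm(DesignMatrix(x, ("a", "b", "const"), 2), y, ridge=1e-10)
        ref = sm.GLM(y, x, family=sm.families.Binomial()).fit().params
        assert np.allclose(mine, ref, atol=1e-5)


def _make_sessions(rng, truth, n=7, t=1_500, noise=True):
    sessions = []
    for i in range(n):
        x = np.column_stack([rng.standard_normal((t, 3)), np.ones(t)])
        p = 1 / (1 + np.exp(-x @ truth))
        y = (rng.random(t) < p).astype(float) if noise else p
        sessions.append(EncodedSession(DesignMatrix(x, ("a", "b", "c", "const"), 3),
                                       y, y, i))
    return sessions


class TestCrossval:
    def test_deterministic_target_gives_r_one(self, rng):
        """When the target IS a logistic function of the design, every fold
        predicts it essentially perfectly."""
        sessions = _make_sessions(rng, np.array([1.0, -0.5, 0.2, -0.3]), noise=False)
        folds = crossval_predict(sessions, k=7, target_mode="smoothed")
        assert all(f.pearson_r > 0.999999 for f in folds)

    def test_null_predictors_give_near_zero_r(self):
        rng = np.random.default_rng(42)
        sessions = []
        for i in range(7):
            x = np.column_stack([rng.standard_normal((19_984 // 7, 3)),
                                 np.ones(19_984 // 7)])
            y = (rng.random(x.shape[0]) < 0.3).astype(float)
            sessions.append(EncodedSession(DesignMatrix(x, ("a", "b", "c", "const"), 3),
                                           y, y, i))
        folds = crossval_predict(sessions, k=7)
        assert np.mean([abs(f.pearson_r) for f in folds]) < 0.02

    def test_seven_folds_per_action(self, rng):
        sessions = _make_sessions(rng, np.array([0.5, 0.0, 0.0, -0.2]))
        folds = crossval_predict(sessions, k=7, action="left")
        assert len(folds) == 7
        assert {f.held_out_session for f in folds} == set(range(7))

    def test_degenerate_held_out_fold_flagged(self, rng):
        sessions = _make_sessions(rng, np.array([0.5, 0.0, 0.0, -0.2]))
        sessions[2].target_smoothed = np.zeros_like(sessions[2].target_smoothed)
        sessions[2].target_raw = np.zeros_like(sessions[2].target_raw)
        folds = crossval_predict(sessions, k=7)
        flagged = [f for f in folds if f.excluded]
        assert [f.held_out_session for f in flagged] == [2]


class TestAggregate:
    @staticmethod
    def _rows(**extra):
        base = {"variant": "baseline", "subject": 0, "game": "minicatch"}
        rows = [
            {**base, "action": "left", "fold": 0, "r": 0.2, **extra},
            {**base, "action": "left", "fold": 1, "r": 0.4, **extra},
        ]
        return pd.DataFrame(rows)

    def test_fold_mean_single_action(self):
        table = aggregate(self._rows())
        assert table.aggregates["r"].tolist() == [pytest.approx(0.3)]

    def test_unused_action_excluded(self):
        df = pd.concat([self._rows(), pd.DataFrame([
            {"variant": "baseline", "subject": 0, "game": "minicatch",
             "action": "right", "fold": 0, "r": 0.9}])], ignore_index=True)
        table = aggregate(df, min_sessions_with_action=0.5,
                          action_usage={"left": 1.0, "right": 0.0})
        assert table.aggregates["r"].tolist() == [pytest.approx(0.3)]

    def test_all_actions_excluded_raises(self):
        with pytest.raises(QBehaveError):
            aggregate(self._rows(), min_sessions_with_action=0.5,
                      action_usage={"left": 0.0})

    def test_last_k_checkpoints_keep_highest_frames(self):
        frames = []
        for ckpt in (0, 1_000, 2_000, 3_000, 4_000):
            df = self._rows()
            df["checkpoint"] = ckpt
            df["r"] = 0.1 if ckpt < 1_000 else 0.5
            frames.append(df)
        table = aggregate(pd.concat(frames, ignore_index=True), last_k_checkpoints=4)
        assert table.aggregates["r"].tolist() == [pytest.approx(0.5)]

    def test_mean_order_folds_then_actions_then_subjects(self):
        rows = []
        for subject, action, rs in [(0, "left", [0.0, 0.2]), (0, "right", [0.6, 0.6]),
                                    (1, "left", [0.4, 0.4]), (1, "right", [0.8, 0.8])]:
            for fold, r in enumerate(rs):
                rows.append({"variant": "v", "subject": subject, "game": "g",
                             "action": action, "fold": fold, "r": r})
        table = aggregate(pd.DataFrame(rows))
        # subject 0: mean(mean(0,.2), mean(.6,.6)) = .35; subject 1: .6 -> overall .475
        assert table.aggregates["r"].tolist() == [pytest.approx(0.475)]


class TestPipelineInvariance:
    def test_positive_rescaling_absorbed_by_zscore(self, rng):
        """z-score -> smooth -> GLM is invariant to scaling all raw Q columns."""
        from qbehave.encoding import make_kernel, smooth

        q = rng.random((400, 3)) * 3 + 1
        kernel = make_kernel(0.26, 45.0)
        a = smooth(zscore_across_actions(q), kernel)
        b = smooth(zscore_across_actions(q * 7.3), kernel)
        assert np.allclose(a, b, atol=1e-10)
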