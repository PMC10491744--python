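import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connectome_cpm.cpm import (
    CPMError,
    NetworkMask,
    _FoldCache,
    _loocv_engine,
    consensus_masks,
    correlate_edges,
    fit_strength_model,
    network_strength,
    predict_score,
    run_loocv,
    select_edges,
    train_full_model,
)
from connectome_cpm.scores import Cohort


# ---------------------------------------------------------------------------
# Independent oracles


def _corr_oracle(x, y):
    """Closed-form covariance Pearson r and two-tailed t-CDF p, pure Python."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0:
        return 0.0, 1.0
    r = cov / math.sqrt(vx * vy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * (1 - stats.t.cdf(abs(t), n - 2))
    return r, p


def naive_loocv(X, y, alpha):
    """Reference LOOCV: per-fold pearsonr selection, polyfit/normal-equation
    fits, no shared statistics.  Deliberately independent of the engine."""
    n = len(y)
    preds = {"positive": np.empty(n), "negative": np.empty(n), "combined": np.empty(n)}
    masks = []
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        Xt, yt = X[tr], y[tr]
        pos = np.zeros(X.shape[1], dtype=bool)
        neg = np.zeros(X.shape[1], dtype=bool)
        for e in range(X.shape[1]):
            if np.ptp(Xt[:, e]) == 0:
                continue
            r, p = stats.pearsonr(Xt[:, e], yt)
            if p < alpha:
                (pos if r > 0 else neg)[e] = True
        masks.append((pos, neg))
        sp, sn = Xt[:, pos].sum(axis=1), Xt[:, neg].sum(axis=1)
        tp, tn = X[i, pos].sum(), X[i, neg].sum()
        for name, cols, test in (
            ("positive", [sp], [tp]),
            ("negative", [sn], [tn]),
            ("combined", [sp, sn], [tp, tn]),
        ):
            keep = [c for c in cols if np.ptp(c) != 0]
            kept_test = [t for c, t in zip(cols, test) if np.ptp(c) != 0]
            if not keep:
                preds[name][i] = yt.mean()
            else:
                design = np.column_stack([np.ones(len(yt))] + keep)
                beta = np.linalg.solve(design.T @ design, design.T @ yt)
                preds[name][i] = beta[0] + sum(b * t for b, t in zip(beta[1:], kept_test))
    return preds, masks


# ---------------------------------------------------------------------------


class TestCorrelateEdges:
    def test_matches_closed_form_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        stats_out = correlate_edges(X, y)
        for e in range(5):
            r, p = _corr_oracle(X[:, e], y)
            assert stats_out.r[e] == pytest.approx(r, rel=1e-10)
            assert stats_out.p[e] == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_edge_equal_to_scores_is_perfectly_correlated(self, rng):
        y = rng.normal(size=6)
        X = np.column_stack([y, rng.normal(size=6)])
        out = correlate_edges(X, y)
        assert out.r[0] == pytest.approx(1.0)
        assert out.p[0] < 1e-12

    def test_constant_edge_gets_zero_r_unit_p(self, rng):
        X = np.column_stack([np.full(6, 2.5), rng.normal(size=6)])
        out = correlate_edges(X, rng.normal(size=6))
        assert out.r[0] == 0.0 and out.p[0] == 1.0

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(CPMError, match="constant"):
            correlate_edges(rng.normal(size=(6, 3)), np.full(6, 4.0))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(CPMError, match=">= 4"):
            correlate_edges(rng.normal(size=(3, 3)), np.arange(3.0))


class TestSelectEdges:
    def _stats(self, r, p):
        from connectome_cpm.cpm import EdgeStats

        return EdgeStats(r=np.asarray(r, float), p=np.asarray(p, float))

    def test_significant_positive_edge_enters_positive_mask(self):
        pos, neg = select_edges(self._stats([0.4], [0.0009]), alpha=0.001)
        assert pos.edges[0] and not neg.edges[0]

    def test_boundary_p_is_excluded_strictly(self):
        pos, neg = select_edges(self._stats([0.4, -0.4], [0.001, 0.001]), alpha=0.001)
        assert not pos.edges.any() and not neg.edges.any()

    def test_all_unit_p_gives_empty_masks(self):
        pos, neg = select_edges(self._stats([0.1, -0.2], [1.0, 1.0]), alpha=0.001)
        assert pos.n_selected == 0 and neg.n_selected == 0

    def test_alpha_one_partitions_nonconstant_edges_by_sign(self, rng):
        X = rng.normal(size=(12, 40))
        y = rng.normal(size=12)
        out = correlate_edges(X, y)
        pos, neg = select_edges(out, alpha=1.0)
        assert not np.any(pos.edges & neg.edges)
        assert np.array_equal(pos.edges | neg.edges, out.r != 0.0)

    def test_masks_are_disjoint(self, rng):
        X = rng.normal(size=(20, 60))
        y = rng.normal(size=20)
        pos, neg = select_edges(correlate_edges(X, y), alpha=0.5)
        assert not np.any(pos.edges & neg.edges)


class TestNetworkStrength:
    def test_empty_mask_gives_zero(self):
        mask = NetworkMask(np.zeros(4, dtype=bool), "positive")
        assert network_strength(np.arange(4.0), mask) == 0.0

    def test_two_edge_arithmetic(self):
        mask = NetworkMask(np.array([True, True, False]), "positive")
        assert network_strength(np.array([0.3, -0.1, 9.0]), mask) == pytest.approx(0.2)

    def test_matches_elementwise_loop(self, rng):
        v = rng.normal(size=50)
        mask = NetworkMask(rng.random(50) < 0.3, "negative")
        loop = sum(v[e] for e in range(50) if mask.edges[e])
        assert network_strength(v, mask) == pytest.approx(loop, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(CPMError, match="length"):
            network_strength(np.zeros(5), NetworkMask(np.zeros(4, dtype=bool), "positive"))

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_strength_is_linear_in_the_edge_vector(self, seed, a, b):
        r = np.random.default_rng(seed)
        v, w = r.normal(size=20), r.normal(size=20)
        mask = NetworkMask(r.random(20) < 0.4, "positive")
        lhs = network_strength(a * v + b * w, mask)
        rhs = a * network_strength(v, mask) + b * network_strength(w, mask)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestFitStrengthModel:
    def test_identity_fit(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        coef = fit_strength_model(s, s)
        assert coef == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_constant_strengths_absorbed_into_intercept(self):
        coef = fit_strength_model(np.full(5, 3.0), np.array([1.0, 2, 3, 4, 5]))
        assert coef == pytest.approx([3.0, 0.0])

    def test_six_point_toy_matches_normal_equations(self, rng):
        S = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        design = np.column_stack([np.ones(6), S])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        coef = fit_strength_model(S, y)
        assert coef == pytest.approx(beta, rel=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(CPMError, match="subjects"):
            fit_strength_model(np.zeros((2, 2)), np.zeros(2))


class TestPredictScore:
    def _model(self, n_edges=6, pos=(0, 1), neg=(2,), coefficients=None):
        from connectome_cpm.cpm import NetworkModel

        pm = np.zeros(n_edges, dtype=bool)
        pm[list(pos)] = True
        nm = np.zeros(n_edges, dtype=bool)
        nm[list(neg)] = True
        coefficients = coefficients or {
            "positive": [0.0, 1.0],
            "negative": [0.0, 1.0],
            "combined": [0.0, 1.0, 0.5],
        }
        return NetworkModel(
            pos_mask=NetworkMask(pm, "positive"),
            neg_mask=NetworkMask(nm, "negative"),
            coefficients={k: np.asarray(v, float) for k, v in coefficients.items()},
            n_nodes=4,
        )

    def test_unit_slope_zero_intercept_returns_strength(self):
        model = self._model()
        v = np.array([2.0, 3.0, 1.0, 0.0, 0.0, 0.0])
        assert predict_score(model, v, "positive") == pytest.approx(5.0)

    def test_empty_masks_predict_the_intercept(self):
        model = self._model(pos=(), neg=(), coefficients={
            "positive": [4.2, 0.0], "negative": [4.2, 0.0], "combined": [4.2, 0.0, 0.0],
        })
        v = np.ones(6)
        for which in ("positive", "negative", "combined"):
            assert predict_score(model, v, which) == pytest.approx(4.2)

    def test_unknown_model_name_rejected(self):
        with pytest.raises(CPMError, match="unknown model"):
            predict_score(self._model(), np.zeros(6), "quadratic")

    def test_training_subject_gets_its_in_sample_fitted_value(self, rng):
        X = rng.normal(size=(12, 20))
        y = rng.normal(size=12)
        cohort = Cohort([f"s{k}" for k in range(12)], X, {"hdrs5": y})
        model = train_full_model(cohort, "hdrs5", alpha=0.3)
        sp = X[:, model.pos_mask.edges].sum(axis=1)
        sn = X[:, model.neg_mask.edges].sum(axis=1)
        c = model.coefficients["combined"]
        fitted = c[0] + c[1] * sp + c[2] * sn
        got = predict_score(model, X, "combined")
        assert np.allclose(got, fitted, rtol=1e-12)


class TestRunLoocv:
    @staticmethod
    def _cohort(X, y):
        return Cohort([f"s{k}" for k in range(len(y))], X, {"hdrs5": np.asarray(y, float)})

    def test_minimal_cohort_yields_one_prediction_per_fold(self, rng):
        X = rng.normal(size=(3, 6))
        y = rng.normal(size=3)
        with pytest.warns(UserWarning, match="fragile"):
            result = run_loocv(self._cohort(X, y), "hdrs5", alpha=0.05)
        for name in ("positive", "negative", "combined"):
            assert result.predictions[name].shape == (3,)

    def test_engine_agrees_with_naive_reference(self, rng):
        X = rng.normal(size=(14, 25))
        y = rng.normal(size=14)
        alpha = 0.1
        result = run_loocv(self._cohort(X, y), "hdrs5", alpha=alpha)
        preds, masks = naive_loocv(X, y, alpha)
        for name in ("positive", "negative", "combined"):
            assert np.allclose(result.predictions[name], preds[name], rtol=1e-9)
        for fold, (pos, neg) in enumerate(masks):
            assert np.array_equal(result.fold_masks[fold][0].edges, pos)
            assert np.array_equal(result.fold_masks[fold][1].edges, neg)

    def test_altering_held_out_score_changes_nothing_in_its_fold(self, small_cohort):
        cohort, _ = small_cohort
        result = run_loocv(cohort, "hdrs5", alpha=0.01)
        for i in (0, cohort.n_subjects // 2, cohort.n_subjects - 1):
            y2 = cohort.score("hdrs5").copy()
            y2[i] += 7.0
            perturbed = Cohort(
                list(cohort.subject_ids), cohort.edge_matrix, {"hdrs5": y2},
            )
            result2 = run_loocv(perturbed, "hdrs5", alpha=0.01)
            assert np.array_equal(
                result.fold_masks[i][0].edges, result2.fold_masks[i][0].edges
            )
            assert np.array_equal(
                result.fold_masks[i][1].edges, result2.fold_masks[i][1].edges
            )
            for name in ("positive", "negative", "combined"):
                assert result.predictions[name][i] == result2.predictions[name][i]

    def test_missing_target_scores_rejected(self, rng):
        X = rng.normal(size=(6, 6))
        y = np.array([1.0, 2, np.nan, 3, 4, 5])
        with pytest.raises(CPMError, match="missing"):
            run_loocv(self._cohort(X, y), "hdrs5")

    def test_concordance_matches_reported_predictions(self, small_cohort):
        cohort, _ = small_cohort
        result = run_loocv(cohort, "hdrs5", alpha=0.01)
        for name in ("positive", "negative", "combined"):
            expected = np.corrcoef(result.predictions[name], result.observed)[0, 1]
            assert result.r[name] == pytest.approx(expected, rel=1e-12)
            expected_rmse = np.sqrt(
                np.mean((result.predictions[name] - result.observed) ** 2)
            )
            assert result.rmse[name] == pytest.approx(expected_rmse, rel=1e-12)


class TestConsensusMasks:
    @staticmethod
    def _mask(indices, sign, n=10):
        m = np.zeros(n, dtype=bool)
        m[list(indices)] = True
        return NetworkMask(m, sign)

    def test_identical_folds_preserve_the_mask(self):
        folds = [
            (self._mask([1, 4], "positive"), self._mask([7], "negative"))
            for _ in range(5)
        ]
        pos, neg = consensus_masks(folds)
        assert pos.edge_indices() == [1, 4] and neg.edge_indices() == [7]

    def test_disjoint_folds_give_empty_consensus(self):
        folds = [
            (self._mask([1], "positive"), self._mask([2], "negative")),
            (self._mask([3], "positive"), self._mask([4], "negative")),
        ]
        pos, neg = consensus_masks(folds)
        assert pos.n_selected == 0 and neg.n_selected == 0

    def test_three_folds_sharing_two_positive_edges(self):
        folds = [
            (self._mask([0, 1, 2], "positive"), self._mask([], "negative")),
            (self._mask([0, 2, 5], "positive"), self._mask([], "negative")),
            (self._mask([0, 2, 8], "positive"), self._mask([], "negative")),
        ]
        pos, _ = consensus_masks(folds)
        assert pos.edge_indices() == [0, 2]

    def test_empty_fold_list_rejected(self):
        with pytest.raises(CPMError, match="fold"):
            consensus_masks([])


class TestFoldCacheInternals:
    def test_prefix_suffix_sums_exclude_the_held_out_row(self, rng):
        X = rng.normal(size=(9, 4))
        cache = _FoldCache(X)
        for i in range(9):
            rest = np.delete(X, i, axis=0)
            assert np.allclose(cache.sx[i], rest.sum(axis=0), rtol=1e-12)

    def test_engine_predictions_do_not_depend_on_score_scale_pathologies(self, rng):
        # integer-valued scores with ties, as rating scales produce
        X = rng.normal(size=(15, 12))
        y = rng.integers(0, 5, size=15).astype(float)
        cache = _FoldCache(X)
        preds, _ = _loocv_engine(y, cache, alpha=0.2)
        ref, _ = naive_loocv(X, y, 0.2)
        for name in ("positive", "negative", "combined"):
            assert np.allclose(preds[name], ref[name], rtol=1e-9)
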