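"""SID model: calibration MLE, scoring formula, RFE behaviour, mode choice."""

import numpy as np
import pytest
from scipy.special import expit

from senescore.io import CountMatrix
from senescore.preprocess import ExpressionMatrix, cpm_log, zscore_genes
from senescore.sid import (
    CalibrationWarning,
    SIDClassifier,
    SidEnsemble,
    SidModel,
    calibrate,
    classify,
    classify_scores,
    score,
    select_mode,
    train_sid,
)


def _grid_mle(f, y, a_range=(-30, 30), b_range=(-30, 30), steps=301, refine=3):
    """Independent 1-D logistic MLE by nested grid search."""
    f = np.asarray(f, float)
    y = np.asarray(y, float)

    def nll(a, b):
        z = a * f + b
        return np.sum(np.logaddexp(0, z) - y * z)

    lo_a, hi_a = a_range
    lo_b, hi_b = b_range
    best = (0.0, 0.0)
    for _ in range(refine):
        aa = np.linspace(lo_a, hi_a, steps)
        bb = np.linspace(lo_b, hi_b, steps)
        vals = np.array([[nll(a, b) for b in bb] for a in aa])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (aa[i], bb[j])
        da, db = (hi_a - lo_a) / (steps - 1), (hi_b - lo_b) / (steps - 1)
        lo_a, hi_a = best[0] - 2 * da, best[0] + 2 * da
        lo_b, hi_b = best[1] - 2 * db, best[1] + 2 * db
    return best


def _zscored(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples, stage="zscored")


class TestCalibrate:
    def test_matches_grid_search_mle(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=200)
        y = (rng.random(200) < expit(1.3 * f - 0.4)).astype(int)
        if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
            pytest.skip("degenerate draw")
        alpha, beta = calibrate(f, y)
        a_ref, b_ref = _grid_mle(f, y)
        assert alpha == pytest.approx(a_ref, abs=5e-3)
        assert beta == pytest.approx(b_ref, abs=5e-3)

    def test_symmetric_decisions_balanced_labels(self):
        # overlapping but informative decisions, symmetric about zero
        f = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        alpha, beta = calibrate(f, y)
        a_ref, b_ref = _grid_mle(f, y)
        assert alpha > 0
        assert beta == pytest.approx(b_ref, abs=1e-2)
        assert abs(beta) < 0.2

    def test_uninformative_decisions_give_flat_score_at_prevalence(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=400)
        y = (rng.random(400) < 0.3).astype(int)
        alpha, beta = calibrate(f, y)
        assert alpha == pytest.approx(0.0, abs=0.15)
        assert expit(beta) == pytest.approx(y.mean(), abs=0.05)

    def test_label_inversion_flips_slope_sign(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=150)
        y = (rng.random(150) < expit(2 * f)).astype(int)
        a_pos, _ = calibrate(f, y)
        a_neg, _ = calibrate(f, 1 - y)
        assert a_pos > 0 > a_neg

    def test_perfect_separation_falls_back_to_capped_slope(self):
        f = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(CalibrationWarning):
            alpha, _ = calibrate(f, y, slope_cap=20.0)
        assert 0 < alpha <= 20.0 / np.std(f) + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate([0.1, 0.2], [1, 1])


class TestScoreFormula:
    @staticmethod
    def _model(weights, genes, alpha, beta, bias=0.0):
        return SidModel(1, genes, np.asarray(weights, float), bias, alpha, beta)

    def test_logistic_midpoint_and_closed_form(self):
        model = self._model([1.0], ["GA"], alpha=1.0, beta=0.0)
        expr = _zscored([[0.0, 1.0]], genes=["GA"])
        res = score(model, expr)
        assert res.sid[0] == pytest.approx(0.5, abs=1e-15)
        model2 = self._model([1.0], ["GA"], alpha=2.0, beta=1.0)
        res2 = score(model2, expr)
        assert res2.sid[1] == pytest.approx(1 / (1 + np.exp(-3.0)), abs=1e-12)
        assert res2.sid[1] == pytest.approx(0.95257, abs=5e-6)

    def test_monotone_in_decision_and_limits(self):
        model = self._model([1.0], ["GA"], alpha=1.5, beta=-0.2)
        f = np.linspace(-40, 40, 81)
        res = score(model, _zscored([f], genes=["GA"]))
        assert np.all(np.diff(res.sid) > 0) or np.all(np.diff(res.sid) >= 0)
        assert res.sid[0] < 1e-15 and res.sid[-1] > 1 - 1e-15
        assert np.array_equal(np.argsort(res.decision), np.argsort(res.sid))

    def test_missing_genes_imputed_with_coverage(self):
        model = self._model([1.0, 2.0], ["GA", "GMISSING"], alpha=1.0, beta=0.0)
        expr = _zscored([[1.0, -1.0]], genes=["GA"])
        res = score(model, expr)
        assert res.feature_coverage == 0.5
        np.testing.assert_allclose(res.decision, [1.0, -1.0])  # missing gene at z=0

    def test_zero_coverage_rejected(self):
        model = self._model([1.0], ["NOPE"], alpha=1.0, beta=0.0)
        with pytest.raises(ValueError, match="feature genes"):
            score(model, _zscored([[1.0, 2.0]], genes=["GA"]))

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        model = self._model(rng.normal(size=3), ["GA", "GB", "GC"], alpha=1.1, beta=0.3)
        values = rng.normal(size=(3, 8))
        expr = _zscored(values, genes=["GA", "GB", "GC"])
        perm = rng.permutation(8)
        expr_p = _zscored(values[:, perm], genes=["GA", "GB", "GC"],
                          samples=[f"S{j}" for j in perm])
        np.testing.assert_array_equal(score(model, expr).sid[perm], score(model, expr_p).sid)


class TestClassify:
    def test_threshold_semantics(self):
        # at exactly the threshold the call is non-senescent; strictly above it
        # the call is senescent
        assert classify_scores([0.5])[0] == 0
        assert classify_scores([0.50001])[0] == 1
        assert classify_scores([0.9, 0.1]).tolist() == [1, 0]

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            classify_scores([0.5], threshold=1.5)

    def test_rethreshold_updates_result(self):
        model = SidModel(1, ["GA"], np.array([1.0]), 0.0, 1.0, 0.0)
        res = score(model, _zscored([[0.2, -0.2]], genes=["GA"]))
        calls = classify(res, threshold=0.4)
        assert calls.tolist() == [1, 1]
        assert res.call.tolist() == [1, 1]


class TestTraining:
    def test_no_elimination_equals_single_svm_fit(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        clf = SIDClassifier(n_features=6, random_state=0).fit(X, y)
        assert clf.elimination_order_ == []
        ref = SVC(kernel="linear", C=1.0, class_weight="balanced").fit(X, y)
        order = np.argsort(clf.feature_idx_)
        np.testing.assert_allclose(clf.coef_[order], np.ravel(ref.coef_), atol=1e-10)
        assert clf.intercept_ == pytest.approx(float(ref.intercept_[0]), abs=1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="single class"):
            SIDClassifier(n_features=2).fit(X, np.ones(10))

    def test_rfe_keeps_planted_separators(self):
        # 2 perfectly separating genes among 50 pure-noise genes
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 52))
        X[:, 0] = y * 2 - 1 + 0.01 * rng.normal(size=n)
        X[:, 1] = -(y * 2 - 1) + 0.01 * rng.normal(size=n)
        with pytest.warns(CalibrationWarning):
            clf = SIDClassifier(n_features=2, random_state=0).fit(X, y)
        assert set(clf.feature_idx_) == {0, 1}

    def test_retraining_is_bit_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 20))
        y = (X[:, :3].sum(axis=1) > 0).astype(int)
        a = SIDClassifier(n_features=5, random_state=3).fit(X, y)
        b = SIDClassifier(n_features=5, random_state=3).fit(X, y)
        assert np.array_equal(a.coef_, b.coef_)
        assert np.array_equal(a.feature_idx_, b.feature_idx_)
        assert (a.alpha_, a.beta_, a.intercept_) == (b.alpha_, b.beta_, b.intercept_)

    def test_train_sid_requires_zscored_and_both_classes(self, tiny_counts):
        expr = cpm_log(tiny_counts)
        with pytest.raises(ValueError, match="z-scored"):
            train_sid(expr, [0, 1, 0, 1], n_features_target=2)
        with pytest.raises(ValueError, match="single class"):
            train_sid(zscore_genes(expr), [1, 1, 1, 1], n_features_target=2)

    def test_n_features_exceeding_genes_rejected(self, tiny_counts):
        expr = zscore_genes(cpm_log(tiny_counts))
        with pytest.raises(ValueError, match="exceeds"):
            train_sid(expr, [0, 1, 0, 1], n_features_target=99)

    def test_cross_fit_calibration_avoids_separation_warning(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(120, 30))
        y = (X[:, 0] + X[:, 1] + 1.2 * rng.normal(size=120) > 0).astype(int)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", CalibrationWarning)
            clf = SIDClassifier(
                n_features=10, cross_fit_calibration=True, random_state=0
            ).fit(X, y)
        assert np.isfinite(clf.alpha_) and clf.alpha_ > 0


class TestSelectMode:
    @staticmethod
    def _single_gene_model(mode_id, gene, flip=False):
        w = np.array([-3.0 if flip else 3.0])
        return SidModel(mode_id, [gene], w, 0.0, 1.0, 0.0)

    def test_singleton_ensemble(self):
        ens = SidEnsemble([self._single_gene_model(4, "GA")])
        expr = _zscored(np.random.default_rng(0).normal(size=(1, 30)), genes=["GA"])
        mode, diag = select_mode(ens, expr)
        assert mode == 4 and set(diag) == {4}

    def test_labeled_selection_by_auroc(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 15)
        ga = labels + 0.01 * rng.normal(size=30)  # perfectly informative
        gb = rng.normal(size=30)  # uninformative
        expr = _zscored(np.vstack([ga, gb]), genes=["GA", "GB"])
        ens = SidEnsemble([
            self._single_gene_model(1, "GB"),
            self._single_gene_model(2, "GA"),
        ])
        mode, diag = select_mode(ens, expr, labels=labels)
        assert mode == 2
        assert diag[2] == pytest.approx(1.0)
        assert diag[1] < 0.8

    def test_unlabeled_selection_prefers_bimodal_scores(self):
        rng = np.random.default_rng(2)
        bimodal = np.concatenate([rng.normal(-3, 0.2, 40), rng.normal(3, 0.2, 40)])
        unimodal = rng.normal(0, 1.0, 80)
        expr = _zscored(np.vstack([bimodal, unimodal]), genes=["GA", "GB"])
        ens = SidEnsemble([
            self._single_gene_model(1, "GB"),
            self._single_gene_model(2, "GA"),
        ])
        mode, diag = select_mode(ens, expr)
        assert mode == 2
        assert diag[2] > diag[1]

    def test_unlabeled_diagnostic_matches_exhaustive_split(self):
        # for 1-D scores the optimal 2-means clustering is a contiguous split:
        # compare against exhaustive enumeration of all split points
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(-1, 0.5, 12), rng.normal(2, 0.5, 12)])
        best = -1.0
        order = np.sort(scores)
        for cut in range(1, len(order)):
            labels = (scores > (order[cut - 1] + order[cut]) / 2).astype(int)
            if labels.min() == labels.max():
                continue
            best = max(best, silhouette_score(scores.reshape(-1, 1), labels))
        from senescore.sid import _bimodality_silhouette

        assert _bimodality_silhouette(scores) == pytest.approx(best, abs=1e-9)

    def test_duplicate_mode_ids_rejected(self):
        m = self._single_gene_model(1, "GA")
        with pytest.raises(ValueError, match="distinct"):
            SidEnsemble([m, self._single_gene_model(1, "GB")])

    def test_empty_ensemble_rejected(self):
        expr = _zscored([[0.0, 1.0]], genes=["GA"])
        with pytest.raises(ValueError, match="empty"):
            select_mode(SidEnsemble([]), expr)


class TestSidResultInvariant:
    def test_sid_equals_logistic_of_decision(self, sc_medium_split):
        res = sc_medium_split["result"]
        model = sc_medium_split["model"]
        np.testing.assert_allclose(
            res.sid, expit(model.alpha * res.decision + model.beta), atol=1e-15
        )
        assert np.array_equal(res.call, (res.sid > 0.5).astype(int))
        assert res.sid.min() >= 0 and res.sid.max() <= 1
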