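"""Senescence identity (SID) scoring models.

A SID model is a linear soft-margin SVM whose feature genes were selected by
recursive feature elimination (RFE): the SVM is refit repeatedly and at each
round the genes with the smallest absolute weights are discarded, until a
target signature size remains. The surviving model's raw decision value
f(x) = w.x + b is mapped to a probability-like score via a one-dimensional
logistic calibration fitted on the training decisions (Platt-style):

    SID = 1 / (1 + exp(-(alpha * f(x) + beta)))

SID lies in [0, 1] and is a strictly monotone transform of f(x) for
alpha > 0, so it preserves the ranking of senescence levels. Cells with
SID > 0.5 are called senescent; SID <= 0.5 is non-senescent. Several
senescence modes — distinct transcriptomic senescence patterns, each with
its own trained model — can be held in an ensemble, and the mode best
matching a dataset selected either by labeled AUROC or by an unlabeled
bimodality diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


class CalibrationWarning(UserWarning):
    """Emitted when logistic calibration falls back to a bounded-slope fit."""


@dataclass
class SidModel:
    """A trained per-mode scorer: feature genes, linear weights, calibration."""

    mode_id: int
    feature_genes: list[str]
    weights: np.ndarray
    bias: float
    alpha: float
    beta: float
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.feature_genes),):
            raise ValueError("weights length must equal number of feature genes")
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("calibration parameters must be finite")


@dataclass
class SidResult:
    """Per-sample decision values, SID scores and senescence calls."""

    sample_ids: list[str]
    decision: np.ndarray
    sid: np.ndarray
    call: np.ndarray
    mode_id: int
    feature_coverage: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "decision": self.decision,
                "sid": self.sid,
                "call": self.call.astype(int),
                "mode_id": self.mode_id,
            }
        )


@dataclass
class SidEnsemble:
    """One model per senescence mode; mode_ids must be distinct."""

    models: list[SidModel]

    def __post_init__(self) -> None:
        ids = [m.mode_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("mode_ids must be distinct")


def calibrate(
    decision,
    labels,
    slope_cap: float = 20.0,
) -> tuple[float, float]:
    """Fit SID = logistic(alpha*f + beta) by maximum likelihood.

    Plain 1-D logistic regression of binary labels on decision values. If the
    classes are perfectly separated the unpenalized MLE diverges; the fit
    then falls back to a bounded-slope MLE with |alpha| capped at
    ``slope_cap`` standard deviations of the decision values (i.e.
    |alpha| <= slope_cap / sd(f)), with a warning.
    """
    f = np.asarray(decision, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if f.shape != y.shape:
        raise ValueError("decision and labels must have equal length")
    if not np.all(np.isfinite(f)):
        raise ValueError("decision values must be finite")
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("labels must contain both classes (0 and 1)")

    def nll_and_grad(params):
        a, b = params
        z = a * f + b
        nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
        p = expit(z)
        return nll, np.array([np.dot(p - y, f), np.sum(p - y)])

    sd = float(np.std(f))
    scale = sd if sd > 0 else 1.0
    separated = f[y == 1].min() > f[y == 0].max() or f[y == 1].max() < f[y == 0].min()
    cap = slope_cap / scale
    if separated:
        warnings.warn(
            "perfectly separated decision values: slope capped at "
            f"|alpha| <= {cap:.4g}",
            CalibrationWarning,
            stacklevel=2,
        )
        bounds = [(-cap, cap), (None, None)]
    else:
        bounds = [(None, None), (None, None)]
    x0 = np.array([1.0 / scale, 0.0])
    res = minimize(nll_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds)
    alpha, beta = float(res.x[0]), float(res.x[1])
    return alpha, beta


class SIDClassifier(ClassifierMixin, BaseEstimator):
    """SVM-RFE senescence classifier with logistic score calibration.

    scikit-learn estimator over samples x genes arrays of z-scored
    log2(CPM+1) expression (see :class:`~senescore.preprocess.CPMLogZScore`).

    Parameters
    ----------
    mode_id : int
        Identifier of the senescence mode this model represents.
    n_features : int
        Target signature size; RFE stops once at most this many genes remain.
    rfe_fraction : float in (0, 1)
        Fraction of the surviving genes eliminated per RFE round
        (``ceil(rfe_fraction * current)``, never overshooting the target).
    svm_cost : float
        Soft-margin cost C of the linear SVM.
    class_weight : "balanced" or dict or None
        Passed to the SVM; the default corrects for senescent cells being a
        minority via inverse-prevalence weights.
    threshold : float in [0, 1]
        SID cut-off for the binary senescent call (strictly greater-than).
    slope_cap : float
        Calibration slope cap under perfect separation (see ``calibrate``).
    cross_fit_calibration : bool
        When True, calibration is fit on out-of-fold decision values from a
        stratified ``calibration_cv``-fold refit of the final SVM instead of
        on the (often perfectly separated) training decisions. Default is
        False: calibration on the shared training cohort.
    calibration_cv : int
        Folds for cross-fitted calibration.
    random_state : int
        Seeds the calibration folds; recorded in the training metadata.

    Attributes
    ----------
    coef_ : ndarray of shape (n_selected,)
        Linear SVM weights over the selected genes.
    intercept_ : float
    feature_idx_ : ndarray
        Column indices of the selected genes, ranked by final |weight|.
    feature_genes_ : list of str
        Names of the selected genes (when feature names were provided).
    alpha_, beta_ : float
        Logistic calibration parameters.
    elimination_order_ : list of list of int
        Column indices removed at each RFE round, first round first.
    """

    def __init__(
        self,
        mode_id: int = 1,
        n_features: int = 100,
        rfe_fraction: float = 0.1,
        svm_cost: float = 1.0,
        class_weight="balanced",
        threshold: float = DEFAULT_THRESHOLD,
        slope_cap: float = 20.0,
        cross_fit_calibration: bool = False,
        calibration_cv: int = 5,
        random_state: int = 0,
    ):
        self.mode_id = mode_id
        self.n_features = n_features
        self.rfe_fraction = rfe_fraction
        self.svm_cost = svm_cost
        self.class_weight = class_weight
        self.threshold = threshold
        self.slope_cap = slope_cap
        self.cross_fit_calibration = cross_fit_calibration
        self.calibration_cv = calibration_cv
        self.random_state = random_state

    def _validate_params_strict(self, n_genes: int) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_features > n_genes:
            raise ValueError(
                f"n_features={self.n_features} exceeds available genes ({n_genes})"
            )
        if not 0 < self.rfe_fraction < 1:
            raise ValueError("rfe_fraction must lie in (0, 1)")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be samples x genes aligned with y")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if not set(classes.astype(float)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        y = y.astype(int)
        n_genes = X.shape[1]
        self._validate_params_strict(n_genes)
        if feature_names is not None and len(feature_names) != n_genes:
            raise ValueError("feature_names length must match gene count")

        surviving = np.arange(n_genes)
        elimination_order: list[list[int]] = []
        svm = None
        while True:
            svm = SVC(kernel="linear", C=self.svm_cost, class_weight=self.class_weight)
            svm.fit(X[:, surviving], y)
            w = np.asarray(svm.coef_).ravel()
            if len(surviving) <= self.n_features:
                break
            n_drop = int(np.ceil(self.rfe_fraction * len(surviving)))
            n_drop = min(n_drop, len(surviving) - self.n_features)
            # ties in |w| broken by column order for reproducibility
            order = np.lexsort((surviving, np.abs(w)))
            drop_local = order[:n_drop]
            elimination_order.append(sorted(int(surviving[i]) for i in drop_local))
            keep = np.ones(len(surviving), dtype=bool)
            keep[drop_local] = False
            surviving = surviving[keep]

        w = np.asarray(svm.coef_).ravel()
        b = float(svm.intercept_[0])
        # final features ranked by decreasing |weight| (ties: column order)
        rank = np.lexsort((surviving, -np.abs(w)))
        self.feature_idx_ = surviving[rank]
        self.coef_ = w[rank]
        self.intercept_ = b
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_genes
        self.elimination_order_ = elimination_order
        if feature_names is not None:
            names = list(feature_names)
            self.feature_genes_ = [str(names[i]) for i in self.feature_idx_]
        else:
            self.feature_genes_ = [str(i) for i in self.feature_idx_]
        if self.cross_fit_calibration:
            decision = self._out_of_fold_decisions(X[:, self.feature_idx_], y)
        else:
            decision = X[:, self.feature_idx_] @ self.coef_ + self.intercept_
        self.alpha_, self.beta_ = calibrate(decision, y, slope_cap=self.slope_cap)
        self.train_meta_ = {
            "n_samples": int(X.shape[0]),
            "n_senescent": int(y.sum()),
            "seed": int(self.random_state),
            "rfe_schedule": {
                "fraction": float(self.rfe_fraction),
                "n_features_target": int(self.n_features),
                "n_rounds": len(elimination_order),
            },
            "svm_cost": float(self.svm_cost),
        }
        return self

    def _out_of_fold_decisions(self, X_sel, y):
        """Decision values from a stratified k-fold refit on the final genes."""
        from sklearn.model_selection import StratifiedKFold

        cv = StratifiedKFold(
            n_splits=self.calibration_cv, shuffle=True, random_state=self.random_state
        )
        oof = np.zeros(len(y))
        for train_idx, test_idx in cv.split(X_sel, y):
            svm = SVC(kernel="linear", C=self.svm_cost, class_weight=self.class_weight)
            svm.fit(X_sel[train_idx], y[train_idx])
            oof[test_idx] = svm.decision_function(X_sel[test_idx])
        return oof

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of genes than at fit time")
        return X[:, self.feature_idx_] @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        sid = self.sid_scores(X)
        return np.column_stack([1.0 - sid, sid])

    def sid_scores(self, X):
        """Calibrated SID scores in [0, 1]."""
        f = self.decision_function(X)
        return expit(self.alpha_ * f + self.beta_)

    def predict(self, X):
        return (self.sid_scores(X) > self.threshold).astype(int)

    def to_model(self) -> SidModel:
        check_is_fitted(self, "coef_")
        return SidModel(
            mode_id=int(self.mode_id),
            feature_genes=list(self.feature_genes_),
            weights=self.coef_.copy(),
            bias=float(self.intercept_),
            alpha=float(self.alpha_),
            beta=float(self.beta_),
            train_meta=dict(self.train_meta_),
        )


def train_sid(
    expr: ExpressionMatrix,
    labels,
    n_features_target: int = 100,
    rfe_fraction: float = 0.1,
    svm_cost: float = 1.0,
    seed: int = 0,
    mode_id: int = 1,
) -> SidModel:
    """Train a SID model on a z-scored genes x samples expression matrix."""
    if expr.stage != "zscored":
        raise ValueError(f"expected z-scored expression, got stage {expr.stage!r}")
    clf = SIDClassifier(
        mode_id=mode_id,
        n_features=n_features_target,
        rfe_fraction=rfe_fraction,
        svm_cost=svm_cost,
        random_state=seed,
    )
    clf.fit(expr.values.T, np.asarray(labels), feature_names=expr.gene_ids)
    return clf.to_model()


def score(model: SidModel, expr: ExpressionMatrix) -> SidResult:
    """Apply a trained model: f(x) = w.x + b, SID = logistic(alpha*f + beta).

    Model genes absent from the query matrix are imputed at z = 0 (the
    per-gene mean after z-scoring); the fraction of model genes found is
    reported as ``feature_coverage`` and must be positive.
    """
    if expr.stage != "zscored":
        raise ValueError(f"expected z-scored expression, got stage {expr.stage!r}")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = np.full(len(model.feature_genes), -1, dtype=np.int64)
    for k, g in enumerate(model.feature_genes):
        rows[k] = index.get(g, -1)
    found = rows >= 0
    coverage = float(found.mean()) if len(rows) else 0.0
    if coverage == 0.0:
        raise ValueError("none of the model's feature genes are present in the query")
    if coverage < 1.0:
        logger.warning(
            "feature coverage %.1f%%: %d/%d model genes found; missing genes imputed at z=0",
            100 * coverage,
            int(found.sum()),
            len(rows),
        )
    x = np.zeros((len(model.feature_genes), expr.n_samples))
    x[found] = expr.values[rows[found]]
    decision = model.weights @ x + model.bias
    sid = expit(model.alpha * decision + model.beta)
    call = classify_scores(sid, DEFAULT_THRESHOLD)
    return SidResult(
        sample_ids=list(expr.sample_ids),
        decision=decision,
        sid=sid,
        call=call,
        mode_id=model.mode_id,
        feature_coverage=coverage,
    )


def classify_scores(sid, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary senescence call: SID strictly greater than the threshold."""
    sid = np.asarray(sid, dtype=np.float64)
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if sid.size and (sid.min() < 0 or sid.max() > 1):
        raise ValueError("SID scores must lie in [0, 1]")
    return (sid > threshold).astype(int)


def classify(result: SidResult, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Re-threshold an existing result; updates ``result.call`` in place."""
    calls = classify_scores(result.sid, threshold)
    result.call = calls
    return calls


def _bimodality_silhouette(scores: np.ndarray, seed: int = 0) -> float:
    """Two-cluster silhouette of 1-D scores; -1 for degenerate distributions."""
    scores = np.asarray(scores, dtype=np.float64).reshape(-1, 1)
    if len(scores) < 3 or np.ptp(scores) == 0:
        return -1.0
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    if len(np.unique(labels)) < 2:
        return -1.0
    return float(silhouette_score(scores, labels))


def select_mode(
    ensemble: SidEnsemble,
    expr: ExpressionMatrix,
    labels=None,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the senescence mode best matching a dataset.

    With labels: the mode whose SID scores maximize AUROC. Without labels:
    the mode whose SID distribution is most bimodal (two-cluster silhouette
    on the 1-D scores) — a heuristic for "this mode's signature splits the
    dataset into two populations". Ties break toward the lowest mode_id.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    diagnostics: dict[int, float] = {}
    for model in ensemble.models:
        result = score(model, expr)
        if labels is not None:
            diagnostics[model.mode_id] = float(roc_auc_score(np.asarray(labels), result.sid))
        else:
            diagnostics[model.mode_id] = _bimodality_silhouette(result.sid, seed=seed)
    best = min(sorted(diagnostics), key=lambda m: (-diagnostics[m], m))
    return best, diagnostics
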