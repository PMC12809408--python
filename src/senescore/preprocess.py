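"""Fixed preprocessing contract: log2(CPM+1) then per-gene z-scoring.

All scoring models in this package consume z-scored log2(CPM+1) expression,
so the same contract is applied to training cohorts and query datasets alike
(z-scores are recomputed per dataset). Pseudobulk aggregation operates on raw
counts, preserving the count sampling model, and is re-normalized afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix

logger = logging.getLogger(__name__)

STAGES = ("raw_counts", "cpm_log", "zscored")


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with a processing-stage tag."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with id lists")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _dense(counts: CountMatrix) -> np.ndarray:
    if sp.issparse(counts.values):
        return np.asarray(counts.values.todense(), dtype=np.float64)
    return np.asarray(counts.values, dtype=np.float64)


def cpm_log(counts: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million then log2(x+1), per sample.

    Every sample column must have a positive total; zero-total samples are
    rejected by identifier so the caller can drop them deliberately.
    """
    values = _dense(counts)
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"zero-total sample(s): {bad}")
    cpm = values / totals * 1e6
    return ExpressionMatrix(
        np.log2(cpm + 1.0), list(counts.gene_ids), list(counts.sample_ids), stage="cpm_log"
    )


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, sd 1 (ddof=1).

    Constant rows cannot be scaled; they are set to all-zeros (the mean of a
    z-scored gene) with a logged warning so trained feature-gene indices stay
    resolvable downstream.
    """
    if expr.stage not in ("cpm_log", "zscored"):
        raise ValueError(f"expected cpm_log input, got stage {expr.stage!r}")
    if expr.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    out = np.zeros_like(expr.values)
    ok = ~constant
    out[ok] = (expr.values[ok] - mean[ok]) / sd[ok]
    if constant.any():
        logger.warning("zeroed %d constant gene row(s) during z-scoring", int(constant.sum()))
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.sample_ids), stage="zscored")


def preprocess_counts(counts: CountMatrix) -> ExpressionMatrix:
    """The full contract: log2(CPM+1) then per-gene z-score."""
    return zscore_genes(cpm_log(counts))


def pseudobulk(counts: CountMatrix, grouping) -> CountMatrix:
    """Sum counts across samples sharing a group label (e.g. donor).

    ``grouping`` maps every sample to exactly one group: a dict, a pandas
    Series indexed by sample id, or a sequence aligned to ``sample_ids``.
    Output columns are the group labels, ordered by first appearance; the
    grand total of counts is conserved exactly.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    if isinstance(grouping, dict):
        missing = [s for s in counts.sample_ids if s not in grouping]
        if missing:
            raise ValueError(f"samples without a group: {missing[:5]}")
        groups = [grouping[s] for s in counts.sample_ids]
    else:
        groups = list(grouping)
        if len(groups) != counts.n_samples:
            raise ValueError("grouping length does not match sample count")
    if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in groups):
        raise ValueError("samples without a group (null label)")
    order: dict[str, int] = {}
    for g in groups:
        order.setdefault(str(g), len(order))
    values = _dense(counts).astype(np.int64)
    out = np.zeros((counts.n_genes, len(order)), dtype=np.int64)
    for j, g in enumerate(groups):
        out[:, order[str(g)]] += values[:, j]
    return CountMatrix(out, list(counts.gene_ids), list(order), layout="dense")


def filter_genes(counts: CountMatrix, min_total: int = 1, min_samples: int = 1) -> CountMatrix:
    """Keep genes with total count >= min_total detected in >= min_samples samples."""
    if min_total < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    values = _dense(counts)
    keep = (values.sum(axis=1) >= min_total) & ((values > 0).sum(axis=1) >= min_samples)
    if not keep.any():
        raise ValueError("gene filter removed all genes")
    idx = np.flatnonzero(keep)
    sub = counts.values[idx] if sp.issparse(counts.values) else counts.values[idx, :]
    return CountMatrix(
        sub, [counts.gene_ids[i] for i in idx], list(counts.sample_ids), layout=counts.layout
    )


class CPMLogZScore(TransformerMixin, BaseEstimator):
    """scikit-learn transformer applying the preprocessing contract.

    Operates on samples x genes arrays (scikit-learn orientation). The
    normalization is per batch by design: CPM depends only on each sample's
    own library size, and z-scores are recomputed across the samples passed
    to ``transform`` — the contract under which the scoring models were
    trained. ``fit`` only records the feature count.
    """

    def __init__(self, zscore: bool = True):
        self.zscore = zscore

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes array")
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            bad = np.flatnonzero(totals.ravel() <= 0).tolist()
            raise ValueError(f"zero-total sample row(s) at index {bad[:5]}")
        out = np.log2(X / totals * 1e6 + 1.0)
        if not self.zscore:
            return out
        if out.shape[0] < 2:
            raise ValueError("z-scoring requires at least 2 samples")
        mean = out.mean(axis=0, keepdims=True)
        sd = out.std(axis=0, ddof=1, keepdims=True)
        z = np.zeros_like(out)
        ok = (sd.ravel() > 0) & np.isfinite(sd.ravel())
        z[:, ok] = (out[:, ok] - mean[:, ok]) / sd[:, ok]
        return z
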