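"""Per-sample gene-set variation scoring of senescence phenotypes.

Phenotype gene sets (SASP, NF-kB targets, proteostasis, cell-cycle arrest,
...) are scored per sample with a gene-set variation statistic: each gene's
expression is first converted to a kernel-smoothed empirical CDF value
across samples (Gaussian kernel, bandwidth = per-gene sd / 4 on log2(CPM+1)
values), then within each sample the genes are ranked and mapped to a
symmetric rank statistic centered at zero. A weighted Kolmogorov–Smirnov
random walk down each sample's ranking — in-set steps proportional to
|stat|^tau, uniform out-of-set decrements — yields the enrichment score,
either as the signed sum of the maximum positive and negative deviations
(``max_diff``, the default) or as the single larger-magnitude deviation
(``two_sided_max``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_ind

from .io import GeneSetCollection, normalize_gene_ids
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeScores:
    """Gene sets x samples enrichment-score matrix."""

    sample_ids: list[str]
    set_names: list[str]
    scores: np.ndarray  # sets x samples
    params: dict

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix shape inconsistent with id lists")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        df = self.to_frame().reset_index(names="set")
        return df.melt(id_vars="set", var_name="sample_id", value_name="score")


def kernel_cdf(expr: ExpressionMatrix) -> np.ndarray:
    """Gaussian-kernel-smoothed empirical CDF of each gene across samples.

    For gene i with values x_i1..x_in and bandwidth h_i = sd(x_i, ddof=1)/4,
    z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i). A constant gene gets
    z = 0.5 in every sample.
    """
    if expr.stage != "cpm_log":
        raise ValueError(f"expected cpm_log expression, got stage {expr.stage!r}")
    n = expr.n_samples
    if n < 3:
        raise ValueError("kernel CDF estimate requires at least 3 samples")
    x = expr.values
    p = expr.n_genes
    z = np.empty_like(x)
    sd = x.std(axis=1, ddof=1)
    for i in range(p):
        if sd[i] > 0:
            h = sd[i] / 4.0
            z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h).mean(axis=1)
        else:
            z[i] = 0.5
    return z


def gene_stat(expr: ExpressionMatrix) -> np.ndarray:
    """Kernel-CDF expression statistic mapped to symmetric per-sample ranks.

    Within each sample, genes are ranked by decreasing :func:`kernel_cdf`
    value (ties broken by input gene order) and rank r in 1..p maps to the
    signed symmetric statistic s = (p - r + 1) - p/2, so the top gene scores
    +p/2, the median ~0 and the bottom gene -(p/2 - 1).
    """
    z = kernel_cdf(expr)
    p, n = z.shape
    stat = np.empty_like(z)
    half = p / 2.0
    for j in range(n):
        order = np.argsort(-z[:, j], kind="stable")
        ranks = np.empty(p, dtype=np.int64)
        ranks[order] = np.arange(1, p + 1)
        stat[:, j] = (p - ranks + 1) - half
    return stat


def gsva_es(
    stat: np.ndarray,
    sets: GeneSetCollection,
    gene_ids,
    tau: float = 1.0,
    statistic: str = "max_diff",
    sample_ids=None,
) -> PhenotypeScores:
    """Weighted KS random-walk enrichment score per gene set and sample.

    ``stat`` is the genes x samples output of :func:`gene_stat` aligned with
    ``gene_ids``. Sets with no matched gene are dropped with a warning; an
    error is raised if nothing matches at all.
    """
    if statistic not in ("max_diff", "two_sided_max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = np.asarray(stat, dtype=np.float64)
    gene_ids = normalize_gene_ids(gene_ids)
    if stat.shape[0] != len(gene_ids):
        raise ValueError("stat rows must align with gene_ids")
    p, n = stat.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n)]
    index = {g: i for i, g in enumerate(gene_ids)}

    matched: list[tuple[str, np.ndarray]] = []
    for name, _, genes in sets.sets:
        idx = np.array(sorted({index[g] for g in normalize_gene_ids(genes) if g in index}),
                       dtype=np.int64)
        if idx.size == 0:
            logger.warning("gene set %r has no genes in the matrix; dropped", name)
            continue
        matched.append((name, idx))
    if not matched:
        raise ValueError("no gene set overlaps the expression matrix")

    scores = np.zeros((len(matched), n))
    absstat = np.abs(stat) ** tau
    for j in range(n):
        order = np.argsort(-stat[:, j], kind="stable")
        w_ordered = absstat[order, j]
        for si, (_, idx) in enumerate(matched):
            in_set = np.zeros(p, dtype=bool)
            in_set[idx] = True
            in_ordered = in_set[order]
            m = idx.size
            denom_in = w_ordered[in_ordered].sum()
            inc = w_ordered / denom_in if denom_in > 0 else np.zeros(p)
            dec = 1.0 / (p - m) if p > m else 0.0
            steps = np.where(in_ordered, inc, -dec)
            walk = np.cumsum(steps)
            mx = max(float(walk.max()), 0.0)
            mn = min(float(walk.min()), 0.0)
            if statistic == "max_diff":
                scores[si, j] = mx + mn
            else:
                scores[si, j] = mx if mx >= -mn else mn
    return PhenotypeScores(
        sample_ids=list(sample_ids),
        set_names=[name for name, _ in matched],
        scores=scores,
        params={"kernel": "gaussian", "tau": float(tau), "statistic": statistic},
    )


def score_phenotypes(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    statistic: str = "max_diff",
) -> PhenotypeScores:
    """Convenience wrapper: gene_stat + gsva_es on a cpm_log matrix."""
    stat = gene_stat(expr)
    return gsva_es(stat, sets, expr.gene_ids, tau=tau, statistic=statistic,
                   sample_ids=expr.sample_ids)


def example_gene_sets() -> GeneSetCollection:
    """Bundled illustrative phenotype gene sets (SASP, NF-kB targets,
    proteostasis loss, cell-cycle arrest).

    These are small example sets assembled for demonstrations and tests;
    they are not an export of any curated database. Users analyzing real
    data should supply their own curated phenotype collections in GMT form.
    """
    from importlib.resources import files

    from .io import read_gmt

    return read_gmt(files("senescore") / "data" / "example_senescence_phenotypes.gmt")


def compare_phenotypes(scores: PhenotypeScores, groups) -> pd.DataFrame:
    """Welch t-test per gene set between two groups, BH-adjusted.

    ``groups`` is aligned with ``scores.sample_ids`` and must have exactly
    two levels with at least two samples each. Returns a table sorted by
    adjusted q-value with columns set, mean_a, mean_b, t, p, q (level "a" is
    the lexically smaller group label).
    """
    from .evaluation import bh_fdr

    groups = np.asarray(groups)
    if groups.shape[0] != len(scores.sample_ids):
        raise ValueError("groups must align with sample_ids")
    levels = sorted(set(str(g) for g in groups))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a = np.array([str(g) == levels[0] for g in groups])
    b = ~a
    if a.sum() < 2 or b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for si, name in enumerate(scores.set_names):
        xa, xb = scores.scores[si, a], scores.scores[si, b]
        t, pval = ttest_ind(xa, xb, equal_var=False)
        if not np.isfinite(t):
            if np.isclose(xa.mean(), xb.mean()):
                t, pval = 0.0, 1.0  # identical constant groups
            else:
                t = np.inf if xa.mean() > xb.mean() else -np.inf
                pval = 0.0
        rows.append((name, float(xa.mean()), float(xb.mean()), float(t), float(pval)))
    table = pd.DataFrame(rows, columns=["set", "mean_a", "mean_b", "t", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("q", kind="stable").reset_index(drop=True)
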