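"""Senescence trajectories: SID-anchored ordering and held-out validation.

The primary ordering ranks cells by SID score (min-max scaled to [0, 1],
root at the least-senescent cell). Its independence from the scoring genes
is checked with a second, expression-driven pseudotime computed on a
held-out gene space that excludes every gene used in SID computation: PCA on
the held-out genes, a k-nearest-neighbor graph, its minimum spanning tree,
and min-max-scaled geodesic distance from a root cell. Concordance between
the two orderings is quantified with Spearman's rank correlation. Genes with
trajectory-correlated kinetics are extracted by tri-cube local averaging of
expression over a uniform pseudotime grid, Spearman trend correlation, and
k-means clustering of the standardized smoothed profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .io import normalize_gene_ids
from .preprocess import ExpressionMatrix
from .sid import SidResult


@dataclass
class Trajectory:
    """Per-cell pseudotime in [0, 1] with ordering and provenance."""

    cell_ids: list[str]
    pseudotime: np.ndarray
    ordering: np.ndarray
    root_cell: str
    method: str  # "sid_rank" | "graph_mst"
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=np.float64)
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        if self.pseudotime.shape != (len(self.cell_ids),):
            raise ValueError("pseudotime length must match cell count")
        if self.pseudotime.min() < 0 or self.pseudotime.max() > 1:
            raise ValueError("pseudotime must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "pseudotime": self.pseudotime, "method": self.method}
        )


@dataclass
class GeneKinetics:
    """Smoothed expression profiles along pseudotime with trend annotations."""

    gene_ids: list[str]
    grid: np.ndarray
    smoothed: np.ndarray  # genes x grid
    trend_correlation: np.ndarray
    flat_flag: np.ndarray
    cluster: np.ndarray


def _stable_ordering(pseudotime: np.ndarray, cell_ids: list[str]) -> np.ndarray:
    """Ascending pseudotime; ties resolved by cell identifier."""
    return np.lexsort((np.asarray(cell_ids, dtype=object), pseudotime))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot scale a constant pseudotime")
    return (x - lo) / (hi - lo)


def sid_pseudotime(result: SidResult) -> Trajectory:
    """Pseudotime = min-max-scaled rank of SID; root = lowest-SID cell."""
    if len(result.sample_ids) < 3:
        raise ValueError("trajectory requires at least 3 cells")
    sid = np.asarray(result.sid, dtype=np.float64)
    if np.ptp(sid) == 0:
        raise ValueError("all SID scores equal; no ordering exists")
    ranks = rankdata(sid, method="average")
    pt = _minmax(ranks)
    ordering = _stable_ordering(pt, result.sample_ids)
    return Trajectory(
        cell_ids=list(result.sample_ids),
        pseudotime=pt,
        ordering=ordering,
        root_cell=result.sample_ids[int(ordering[0])],
        method="sid_rank",
    )


def graph_pseudotime(
    expr: ExpressionMatrix,
    exclude_genes=(),
    root_hint: str | None = None,
    k_neighbors: int = 15,
    n_components: int = 10,
    seed: int = 0,
) -> Trajectory:
    """Expression-driven pseudotime on a held-out gene space.

    PCA on the genes remaining after exclusion, a symmetrized k-nearest-
    neighbor distance graph, its minimum spanning tree, and geodesic
    distance from the root (min-max scaled). Excluded genes never enter the
    computation; the matrix is subset before PCA and the exclusion list is
    recorded on the result.
    """
    if expr.stage != "zscored":
        raise ValueError(f"expected z-scored expression, got stage {expr.stage!r}")
    exclude = set(normalize_gene_ids(exclude_genes))
    keep = [i for i, g in enumerate(expr.gene_ids) if g not in exclude]
    if len(keep) < 10:
        raise ValueError(
            f"only {len(keep)} genes remain after exclusion; need at least 10"
        )
    n_cells = expr.n_samples
    if n_cells < 3:
        raise ValueError("trajectory requires at least 3 cells")
    if not 1 <= k_neighbors < n_cells:
        raise ValueError("k_neighbors must satisfy 1 <= k < n_cells")
    X = expr.values[keep].T  # cells x held-out genes
    n_comp = min(n_components, min(X.shape) - 1)
    if n_comp >= 1:
        X = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    graph = kneighbors_graph(X, k_neighbors, mode="distance", include_self=False)
    graph = graph.maximum(graph.T)
    n_comp_graph, labels = connected_components(graph, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"k-nearest-neighbor graph disconnected into {n_comp_graph} "
            f"components of sizes {sizes}; increase k_neighbors"
        )
    mst = minimum_spanning_tree(graph)
    mst = mst.maximum(mst.T)
    if root_hint is None:
        root_idx = 0
    else:
        try:
            root_idx = expr.sample_ids.index(str(root_hint))
        except ValueError as exc:
            raise ValueError(f"root cell {root_hint!r} not in matrix") from exc
    dist = dijkstra(mst, directed=False, indices=root_idx)
    pt = _minmax(dist)
    ordering = _stable_ordering(pt, expr.sample_ids)
    return Trajectory(
        cell_ids=list(expr.sample_ids),
        pseudotime=pt,
        ordering=ordering,
        root_cell=expr.sample_ids[root_idx],
        method="graph_mst",
        excluded_genes=sorted(exclude),
    )


def concordance(a: Trajectory, b: Trajectory) -> dict[str, float]:
    """Spearman rank correlation between two pseudotimes on the same cells."""
    if set(a.cell_ids) != set(b.cell_ids):
        raise ValueError("trajectories cover different cell sets")
    b_index = {c: i for i, c in enumerate(b.cell_ids)}
    b_pt = np.array([b.pseudotime[b_index[c]] for c in a.cell_ids])
    rho, p = spearmanr(a.pseudotime, b_pt)
    return {"rho": float(rho), "p": float(p)}


def gene_kinetics(
    expr: ExpressionMatrix,
    traj: Trajectory,
    grid_size: int = 100,
    window_fraction: float = 0.3,
    n_clusters: int = 4,
    seed: int = 0,
) -> GeneKinetics:
    """Tri-cube-smoothed expression along pseudotime, trends and clusters.

    At each of ``grid_size`` uniform grid points the expression of every
    gene is averaged over cells within a window of ``window_fraction`` of
    the pseudotime range (tri-cube weights). The trend correlation is the
    Spearman correlation of raw expression with pseudotime; genes constant
    across cells get correlation 0 and a flat flag. Profiles (standardized)
    are clustered by k-means with a fixed seed.
    """
    if expr.stage != "cpm_log":
        raise ValueError(f"expected cpm_log expression, got stage {expr.stage!r}")
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    if list(expr.sample_ids) != list(traj.cell_ids):
        raise ValueError("expression samples must match trajectory cells")
    t = traj.pseudotime
    span = float(np.ptp(t))
    if span == 0:
        raise ValueError("constant pseudotime")
    half = window_fraction * span / 2.0
    grid = np.linspace(t.min(), t.max(), grid_size)
    x = expr.values  # genes x cells
    smoothed = np.empty((expr.n_genes, grid_size))
    for k, g in enumerate(grid):
        u = np.abs(t - g) / half
        w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
        total = w.sum()
        if total == 0:
            raise ValueError(
                f"degenerate window: no cells within {half:.3g} of grid point {g:.3g}"
            )
        smoothed[:, k] = x @ w / total
    trend = np.zeros(expr.n_genes)
    flat = np.zeros(expr.n_genes, dtype=bool)
    for i in range(expr.n_genes):
        if np.ptp(x[i]) == 0:
            flat[i] = True
            continue
        trend[i] = spearmanr(x[i], t)[0]
    profiles = smoothed - smoothed.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    np.divide(profiles, sd, out=profiles, where=sd > 0)
    k = min(n_clusters, expr.n_genes)
    clusters = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(profiles)
    return GeneKinetics(
        gene_ids=list(expr.gene_ids),
        grid=grid,
        smoothed=smoothed,
        trend_correlation=trend,
        flat_flag=flat,
        cluster=clusters.astype(int),
    )
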