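"""Expression pattern discovery: scaled PCA with SVD imputation and
correlation-metric clustering.

Profiles (genes x ordered timepoints) are analysed three ways, matching
the ClustVis / Morpheus conventions widely used for qPCR panels:

* PCA on unit-variance-scaled rows, computed by SVD with iterative
  imputation of missing cells, plus 95% prediction ellipses per group;
* agglomerative hierarchical clustering with one-minus-Pearson distance
  and average linkage (UPGMA);
* k-means with the same metric, realized by z-scoring rows so that
  squared Euclidean distance is proportional to 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans


@dataclass
class PcaResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # columns x components
    variance_explained: np.ndarray  # percent, sums to 100 over all components
    n_iterations: int
    converged: bool
    imputed: pd.DataFrame | None = None  # input with missing cells filled in


@dataclass
class ClusterResult:
    method: str  # "hierarchical_average" or "kmeans"
    assignments: dict  # gene -> cluster id (1-based)
    k: int
    linkage: np.ndarray | None = None  # scipy linkage matrix (hierarchical)
    labels: list | None = None


@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray  # descending
    rotation_deg: float
    degenerate: bool = False


def unit_variance_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its standard deviation (no centering).

    Missing values are ignored in the SD; a row needs >= 2 observed
    values and non-zero SD.
    """
    m = matrix.astype(float)
    sds = m.std(axis=1, ddof=1)
    counts = m.notna().sum(axis=1)
    bad = m.index[(counts < 2) | (sds == 0) | sds.isna()]
    if len(bad):
        raise ValueError(f"rows with zero or undefined SD: {list(bad)}")
    return m.div(sds, axis=0)


def pca_svd_impute(
    matrix: pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PcaResult:
    """Column-centered PCA by SVD, imputing missing cells iteratively.

    Missing cells start at their row mean; each round centers columns,
    takes the SVD, refills the missing cells from the rank-``n_components``
    reconstruction, and repeats until the largest refill change is below
    ``tol`` (or ``max_iter`` rounds, flagged as non-converged). A complete
    matrix reduces to plain centered SVD in a single pass.
    """
    X = matrix.astype(float).to_numpy()
    mask = np.isnan(X)
    if mask.mean() >= 0.5:
        raise ValueError("more than 50% of cells are missing")
    filled = X.copy()
    if mask.any():
        row_means = np.nanmean(X, axis=1)
        filled[mask] = np.take(row_means, np.nonzero(mask)[0])
    n_iter, converged = 0, True
    if mask.any():
        converged = False
        for n_iter in range(1, max_iter + 1):
            col_means = filled.mean(axis=0)
            centered = filled - col_means
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            rank = min(n_components, len(s))
            recon = (u[:, :rank] * s[:rank]) @ vt[:rank] + col_means
            delta = np.max(np.abs(recon[mask] - filled[mask]))
            filled[mask] = recon[mask]
            if delta < tol:
                converged = True
                break
    col_means = filled.mean(axis=0)
    u, s, vt = np.linalg.svd(filled - col_means, full_matrices=False)
    var = s**2
    var_pct = 100.0 * var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comps)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=comps)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_pct,
        n_iterations=n_iter,
        converged=converged,
        imputed=pd.DataFrame(filled, index=matrix.index, columns=matrix.columns),
    )


def prediction_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> Ellipse:
    """Prediction ellipse for one group of 2-D scores.

    Built from the group mean and sample covariance, with the axes scaled
    by sqrt of the chi-square quantile at ``level`` on 2 degrees of
    freedom (the region expected to contain a new observation with
    probability ``level`` under a bivariate normal).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores_2d must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("prediction ellipse needs at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    if np.all(eigvals < 1e-15):
        return Ellipse(center, np.zeros(2), 0.0, degenerate=True)
    semi = np.sqrt(np.maximum(eigvals, 0.0) * q)
    rotation = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
    return Ellipse(center, semi, rotation)


def group_ellipses(
    scores: pd.DataFrame, groups: dict, level: float = 0.95
) -> dict:
    """95% prediction ellipse per group (groups with <3 points skipped)."""
    out = {}
    pcs = scores.iloc[:, :2]
    for name, members in groups.items():
        pts = pcs.loc[[m for m in members if m in pcs.index]].to_numpy()
        if pts.shape[0] < 3:
            continue
        out[name] = prediction_ellipse(pts, level)
    return out


def pearson_distance(profiles: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """One-minus-Pearson distance between rows, pairwise-complete.

    d = 1 - r lies in [0, 2]; pairs with fewer than ``min_overlap``
    shared observed timepoints get a missing distance.
    """
    corr = profiles.T.corr(method="pearson", min_periods=min_overlap)
    d = 1.0 - corr
    np.fill_diagonal(d.values, 0.0)
    return d


def hclust_average(dist: pd.DataFrame) -> ClusterResult:
    """UPGMA (average linkage) on a precomputed distance matrix."""
    d = dist.astype(float)
    if d.isna().any().any():
        raise ValueError("distance matrix contains missing values")
    condensed = squareform(d.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return ClusterResult(
        method="hierarchical_average",
        assignments={},
        k=0,
        linkage=Z,
        labels=list(d.index),
    )


def cut_tree(result: ClusterResult, k: int) -> dict:
    """Cut a hierarchical tree into k flat clusters (1-based ids)."""
    if result.linkage is None:
        raise ValueError("cut_tree requires a hierarchical result")
    flat = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.labels, (int(c) for c in flat)))


def cophenetic_distances(result: ClusterResult) -> np.ndarray:
    if result.linkage is None:
        raise ValueError("cophenetic distances require a hierarchical result")
    return hierarchy.cophenet(result.linkage)


def to_newick(result: ClusterResult) -> str:
    """Serialize a hierarchical tree as Newick with merge-height branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    labels = result.labels

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """k-means under the one-minus-Pearson metric.

    Rows are z-scored (mean 0, SD 1), which makes squared Euclidean
    distance proportional to 1 - r, so standard Lloyd k-means optimizes
    the correlation criterion. Best of ``n_restarts`` seeded runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError("k cannot exceed the number of genes")
    m = profiles.astype(float)
    if m.isna().any().any():
        m = m.apply(lambda row: row.fillna(row.mean()), axis=1)
    z = m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    # relabel clusters by order of first appearance for determinism
    remap, nxt = {}, 1
    assignments = {}
    for gene, lab in zip(profiles.index, labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        assignments[gene] = remap[lab]
    return ClusterResult(method="kmeans", assignments=assignments, k=k)


def profile_matrix(
    relexpr: pd.DataFrame, species: str | None = None, per_timepoint_means: bool = True
) -> pd.DataFrame:
    """Genes x timepoints matrix of mean relative expression.

    The clustering layer runs on 2^-dCt values; by default profiles are
    per-timepoint replicate means (one column per timepoint), optionally
    all individual samples.
    """
    sub = relexpr if species is None else relexpr[relexpr["species"] == species]
    if per_timepoint_means:
        return (
            sub.pivot_table(
                index="gene", columns="timepoint_h", values="rel_expr", aggfunc="mean"
            )
            .sort_index(axis=1)
        )
    wide = sub.pivot(index="gene", columns="sample_id", values="rel_expr")
    order = (
        sub[["sample_id", "timepoint_h", "replicate"]]
        .drop_duplicates()
        .sort_values(["timepoint_h", "replicate"])["sample_id"]
    )
    return wide[order]
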