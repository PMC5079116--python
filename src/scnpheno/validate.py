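"""Cluster-quality and ordination statistics for phenotype validation.

Silhouette scores, covariance PCA with deterministic loading signs, classical
(Torgerson) multidimensional scaling, correlation-distance hierarchical gene
modules, and the Wilcoxon rank-sum test used for spatial positioning
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .data import ExpressionMatrix


# ---------------------------------------------------------------- silhouette
@dataclass
class SilhouetteResult:
    """Per-item silhouette s(i) = (b - a) / max(a, b) and per-cluster means.

    a(i) is the mean dissimilarity of item i to the other members of its own
    cluster (self excluded); b(i) is the smallest mean dissimilarity to any
    other cluster.  Singleton clusters score 0 by convention.
    """

    s: pd.Series
    a: pd.Series
    b: pd.Series
    cluster_means: pd.Series


def silhouette(labels: pd.Series, d: pd.DataFrame) -> SilhouetteResult:
    labels = pd.Series(labels)
    d = d.loc[labels.index, labels.index]
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    uniq = sorted(labels.unique().tolist())
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    lab = labels.to_numpy()
    n = len(lab)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    masks = {c: lab == c for c in uniq}
    for i in range(n):
        own = masks[lab[i]].copy()
        own[i] = False
        if not own.any():  # singleton
            a[i] = 0.0
            b[i] = 0.0
            s[i] = 0.0
            continue
        a[i] = dm[i, own].mean()
        b[i] = min(dm[i, masks[c]].mean() for c in uniq if c != lab[i])
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    s_series = pd.Series(s, index=labels.index)
    cluster_means = pd.Series(
        {c: float(s_series[labels == c].mean()) for c in uniq}
    ).sort_index()
    return SilhouetteResult(
        s=s_series,
        a=pd.Series(a, index=labels.index),
        b=pd.Series(b, index=labels.index),
        cluster_means=cluster_means,
    )


# ----------------------------------------------------------------------- PCA
@dataclass
class PcaResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray
    gene_means: pd.Series
    imputed: bool = False

    def retained_variance(self, k: int) -> float:
        return float(self.variance_fraction[:k].sum())


def pca(x: ExpressionMatrix | pd.DataFrame) -> PcaResult:
    """Covariance PCA of cells in gene space.

    Input is genes x cells; observations are cells.  Missing values are
    imputed with the gene-wise mean (flagged in the result).  Genes are
    mean-centered but not rescaled — -ddCt units are already comparable
    cycles.  Loading signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    vals = (x.values if isinstance(x, ExpressionMatrix) else x).copy()
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 cells")
    imputed = bool(vals.isna().any().any())
    if imputed:
        gene_means_for_impute = vals.mean(axis=1, skipna=True)
        vals = vals.apply(lambda row: row.fillna(gene_means_for_impute[row.name]), axis=1)
    nondegenerate = vals.std(axis=1, ddof=0) > 0
    if nondegenerate.sum() < 2:
        raise ValueError("PCA needs at least 2 non-degenerate genes")
    gene_means = vals.mean(axis=1)
    centered = vals.sub(gene_means, axis=0)
    mat = centered.T.to_numpy()  # cells x genes
    u, sing, vt = np.linalg.svd(mat, full_matrices=False)
    var = sing**2
    total = var.sum()
    if total == 0:
        raise ValueError("data matrix has zero variance")
    loadings = vt.T  # genes x components
    # deterministic sign: largest-|loading| positive per component
    for j in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
            u[:, j] = -u[:, j]
    scores = u * sing
    comp_ids = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=vals.columns, columns=comp_ids),
        loadings=pd.DataFrame(loadings, index=vals.index, columns=comp_ids),
        variance_fraction=var / total,
        gene_means=gene_means,
        imputed=imputed,
    )


# --------------------------------------------------------------- classic MDS
@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # items x k
    eigenvalues: np.ndarray
    stress: float  # residual (unrecovered) squared-distance fraction


def classical_mds(d: pd.DataFrame, k: int = 2) -> MdsResult:
    """Torgerson double-centering eigen-embedding of a dissimilarity matrix.

    Negative eigenvalues (non-Euclidean part) are truncated; if fewer than
    ``k`` positive eigenvalues exist, the embedding dimension is reduced with
    a warning.  Coordinates are centered at the origin.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (dm**2) @ j
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-12 * abs(vals[0]) if n else 0)
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing embedding to k={n_pos}")
        k = max(n_pos, 1)
    use = min(k, n_pos) if n_pos else 1
    coords = vecs[:, :use] * np.sqrt(np.clip(vals[:use], 0, None))
    for jcol in range(coords.shape[1]):  # deterministic reflection
        imax = int(np.argmax(np.abs(coords[:, jcol])))
        if coords[imax, jcol] < 0:
            coords[:, jcol] = -coords[:, jcol]
    total = float(np.clip(vals, 0, None).sum())
    recovered = float(np.clip(vals[:use], 0, None).sum())
    stress = 0.0 if total == 0 else 1.0 - recovered / total
    return MdsResult(
        coordinates=pd.DataFrame(
            coords, index=d.index, columns=[f"MDS{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=vals,
        stress=stress,
    )


# -------------------------------------------------------------- gene modules
@dataclass
class GeneModuleSet:
    modules: pd.Series  # gene -> module id (1..k)
    linkage: np.ndarray
    k: int
    excluded: list = field(default_factory=list)


def gene_modules(x: ExpressionMatrix | pd.DataFrame, k: int = 4) -> GeneModuleSet:
    """Hierarchical gene modules with distance 1 - r and average linkage.

    Constant genes (undefined correlation) are excluded with a warning; the
    dendrogram is cut into ``k`` modules, which are numbered deterministically
    by the first gene label (in input order) they contain.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vals = x.values if isinstance(x, ExpressionMatrix) else x
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = vals.T.corr(min_periods=3)
    constant = vals.std(axis=1, ddof=0, skipna=True) == 0
    undefined = r.isna().all(axis=1) | constant
    excluded = vals.index[undefined].tolist()
    if excluded:
        warnings.warn(f"excluding constant/undefined genes from clustering: {excluded}")
    keep = [g for g in vals.index if g not in excluded]
    r = r.loc[keep, keep].fillna(0.0)
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=min(k, len(keep)), criterion="maxclust")
    seen: dict[int, int] = {}
    renum = []
    for lab in raw:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        renum.append(seen[lab])
    return GeneModuleSet(
        modules=pd.Series(renum, index=pd.Index(keep)),
        linkage=link,
        k=min(k, len(keep)),
        excluded=excluded,
    )


# ---------------------------------------------------------- rank-sum testing
def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on two position samples.

    Exact enumeration when n_A + n_B <= 20 with no ties, otherwise the normal
    approximation with midrank tie correction and continuity correction.
    Returns (W, p) where W is the rank-sum of sample A.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both groups; p = 1")
        w = a.size * (combined.size + 1) / 2.0
        return float(w), 1.0
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size <= 20) and not has_ties
    res = mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum of A
    return w, float(min(res.pvalue, 1.0))
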