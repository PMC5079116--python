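"""Correlation matrices, permutation-calibrated thresholds and thresholded graphs.

Similarity between transcriptional profiles — of two cells across genes, or of
two genes across cells — is the Pearson correlation on pairwise-complete
observations (non-detects are missing under the default policy).  Graphs keep
an edge only where the correlation clears a threshold; the study-level
defaults are the printed constants r > 0.5 for gene graphs (strict) and
r >= 0.5 for cell graphs, and `permutation_threshold` re-derives empirical
null quantiles for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_from_seed
from .data import ExpressionMatrix
from .graph import Graph

GENE_THRESHOLD = 0.5  # strict (>)
CELL_THRESHOLD = 0.5  # non-strict (>=)
MIN_SHARED_OBS = 10


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix plus pairwise-complete observation counts."""

    r: pd.DataFrame
    n_obs: pd.DataFrame
    axis: str  # "genes" or "cells"


def _profiles(x: ExpressionMatrix | pd.DataFrame, axis: str) -> pd.DataFrame:
    vals = x.values if isinstance(x, ExpressionMatrix) else x
    if axis == "genes":
        return vals.T  # observations = cells, variables = genes
    if axis == "cells":
        return vals  # observations = genes, variables = cells
    raise ValueError("axis must be 'genes' or 'cells'")


def pearson_matrix(
    x: ExpressionMatrix | pd.DataFrame, axis: str, min_obs: int = MIN_SHARED_OBS
) -> CorrelationMatrix:
    """All-pairs Pearson correlation over genes or cells.

    Pairs with fewer than ``min_obs`` shared (pairwise-complete) observations,
    and pairs involving a zero-variance profile, are NA.
    """
    obs = _profiles(x, axis)
    if min_obs < 3:
        raise ValueError("min_obs must be at least 3 for a defined correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = obs.corr(method="pearson", min_periods=min_obs)
    present = obs.notna().astype(float)
    n_obs = present.T @ present
    zero_var = obs.std(ddof=0, skipna=True) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance profiles give NA correlations: {obs.columns[zero_var].tolist()}"
        )
    np.fill_diagonal(r.values, np.where(n_obs.to_numpy().diagonal() >= min_obs, 1.0, np.nan))
    return CorrelationMatrix(r=r, n_obs=n_obs.astype(int), axis=axis)


@dataclass
class NullThreshold:
    """Permutation-null correlation quantile.

    Each permutation shuffles every row of the expression matrix independently
    across columns, destroying gene-gene and cell-cell covariance while
    preserving each gene's marginal distribution.
    """

    threshold: float
    quantile: float
    n_permutations: int
    mode: str  # "pooled" or "familywise"
    seed: int | None
    per_permutation_max: np.ndarray = field(repr=False, default=None)
    null_summary: dict = field(default_factory=dict)


def permutation_threshold(
    x: ExpressionMatrix | pd.DataFrame,
    axis: str,
    n_perm: int = 100,
    quantile: float = 0.95,
    seed: int | None = None,
    mode: str = "pooled",
    min_obs: int = MIN_SHARED_OBS,
) -> NullThreshold:
    """Empirical significance threshold for pairwise correlations.

    mode="pooled" takes the requested quantile of all pairwise r pooled over
    permutations; mode="familywise" takes it over the per-permutation maximum.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if mode not in ("pooled", "familywise"):
        raise ValueError("mode must be 'pooled' or 'familywise'")
    rng = rng_from_seed(seed)
    vals = (x.values if isinstance(x, ExpressionMatrix) else x).to_numpy()

    pooled = []
    per_max = np.empty(n_perm)
    iu = None
    for p in range(n_perm):
        shuffled = np.empty_like(vals)
        for i in range(vals.shape[0]):
            shuffled[i] = vals[i, rng.permutation(vals.shape[1])]
        df = pd.DataFrame(shuffled)
        cm = pearson_matrix(df, axis=axis, min_obs=min_obs)
        rmat = cm.r.to_numpy()
        if iu is None:
            iu = np.triu_indices_from(rmat, k=1)
        vec = rmat[iu]
        vec = vec[~np.isnan(vec)]
        pooled.append(vec)
        per_max[p] = np.nanmax(vec) if vec.size else np.nan
    pooled = np.concatenate(pooled)
    if mode == "pooled":
        thr = float(np.quantile(pooled, quantile))
    else:
        thr = float(np.nanquantile(per_max, quantile))
    return NullThreshold(
        threshold=thr,
        quantile=quantile,
        n_permutations=n_perm,
        mode=mode,
        seed=seed,
        per_permutation_max=per_max,
        null_summary={
            "null_mean": float(np.mean(pooled)),
            "null_sd": float(np.std(pooled)),
            "null_q95": float(np.quantile(pooled, 0.95)),
            "null_q99": float(np.quantile(pooled, 0.99)),
        },
    )


def graph_from_correlations(
    c: CorrelationMatrix, threshold: float, strict: bool = True
) -> Graph:
    """Threshold a correlation matrix into an undirected graph.

    Edge (i, j) is present iff r_ij > threshold (strict) or >= threshold;
    NA correlations never produce edges.  Edge weight = r_ij.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    labels = list(c.r.index)
    g = Graph(labels)
    rmat = c.r.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rij = rmat[i, j]
            if np.isnan(rij):
                continue
            if (rij > threshold) if strict else (rij >= threshold):
                g.add_edge(labels[i], labels[j], rij)
    g.meta = {"threshold": threshold, "strict": strict, "axis": c.axis}
    return g


def gene_network(
    x: ExpressionMatrix, threshold: float = GENE_THRESHOLD, min_obs: int = MIN_SHARED_OBS
) -> Graph:
    """Gene correlation graph at the study default r > 0.5 (strict)."""
    return graph_from_correlations(pearson_matrix(x, "genes", min_obs), threshold, strict=True)


def cell_network(
    x: ExpressionMatrix, threshold: float = CELL_THRESHOLD, min_obs: int = MIN_SHARED_OBS
) -> Graph:
    """Cell correlation graph at the study default r >= 0.5 (non-strict)."""
    return graph_from_correlations(pearson_matrix(x, "cells", min_obs), threshold, strict=False)


def conditional_gene_network(
    x: ExpressionMatrix,
    cell_filter,
    threshold: float = GENE_THRESHOLD,
    min_cells: int = 10,
    min_obs: int = MIN_SHARED_OBS,
    strict: bool = True,
) -> Graph:
    """Gene graph restricted to the cells passing ``cell_filter``.

    ``cell_filter`` is either a boolean Series indexed by cell or a predicate
    applied to each cell label.  Used e.g. to build the Vip+ subnetwork from
    the positive-call mask of Vip.
    """
    if isinstance(cell_filter, pd.Series):
        mask = cell_filter.reindex(x.values.columns).fillna(False).astype(bool)
        name = cell_filter.name or "boolean mask"
    else:
        mask = pd.Series([bool(cell_filter(c)) for c in x.values.columns], index=x.values.columns)
        name = getattr(cell_filter, "__name__", "predicate")
    cells = mask.index[mask].tolist()
    if len(cells) < min_cells:
        raise ValueError(
            f"cell filter '{name}' keeps {len(cells)} cells; at least {min_cells} required"
        )
    sub = ExpressionMatrix(values=x.values[cells], stage=x.stage, provenance=dict(x.provenance))
    g = graph_from_correlations(pearson_matrix(sub, "genes", min_obs), threshold, strict=strict)
    g.meta["subset_size"] = len(cells)
    g.meta["cell_filter"] = name
    return g


class _DisjointSet:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def minimum_spanning_tree(d: pd.DataFrame) -> Graph:
    """Kruskal MST over a symmetric dissimilarity matrix.

    Ties break lexicographically on the (string) node-pair labels, so the tree
    is deterministic.  NA dissimilarities are treated as absent edges; if the
    structure is disconnected a spanning forest is returned with a warning.
    """
    labels = list(d.index)
    edges = []
    dm = d.to_numpy(dtype=float)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not np.isnan(dm[i, j]):
                edges.append((dm[i, j], str(labels[i]), str(labels[j]), labels[i], labels[j]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    tree = Graph(labels)
    ds = _DisjointSet(labels)
    for w, _, _, u, v in edges:
        if ds.union(u, v):
            tree.add_edge(u, v, w)
    if tree.n_edges < len(labels) - 1:
        warnings.warn("dissimilarity structure is disconnected; returning a spanning forest")
    return tree


def correlation_dissimilarity(c: CorrelationMatrix) -> pd.DataFrame:
    """The 1 - r dissimilarity used for MSTs and MDS of profiles."""
    d = 1.0 - c.r
    np.fill_diagonal(d.values, 0.0)
    return d
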