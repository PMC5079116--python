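"""Quality control and the two-step -ddCt normalization.

The normalization follows the standard comparative-Ct scheme for single-cell
qPCR panels: each cell's Ct values are first referenced to the mean of a small
set of stable housekeeping genes (giving -dCt, where higher means more
expressed), then each gene is median-centered across all retained cells from
both treatment groups (giving -ddCt, so zero is the per-gene median).  A
modified z-value, -ddCt divided by the per-gene population SD, is used for
display; because that rescaling is affine per gene it leaves cell-cell Pearson
correlations unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CtMatrix, ExpressionMatrix, QcReport


@dataclass
class QcRules:
    """Thresholds for sample/assay exclusion.

    max_cell_nondetect_frac : cell excluded ("signal") above this fraction of
        non-detected assays.
    require_housekeeping : cell excluded ("failed_reaction") if any
        housekeeping gene failed to amplify.
    max_gene_nondetect_frac : gene excluded ("signal") if non-detected in more
        than this fraction of cells.
    contaminated_genes : assays to drop outright ("contamination").
    """

    max_cell_nondetect_frac: float = 0.7
    require_housekeeping: bool = True
    max_gene_nondetect_frac: float = 0.9
    contaminated_genes: list = field(default_factory=list)

    @classmethod
    def disabled(cls) -> "QcRules":
        return cls(
            max_cell_nondetect_frac=1.0,
            require_housekeeping=False,
            max_gene_nondetect_frac=1.0,
            contaminated_genes=[],
        )


def qc_filter(ct: CtMatrix, rules: QcRules | None = None) -> tuple[CtMatrix, QcReport]:
    """Apply QC rules; returns the filtered matrix plus a reconciling report.

    Cells with every assay non-detected are flagged ``loading`` (nothing was
    loaded), cells failing the housekeeping rule ``failed_reaction``, and
    cells over the non-detect ceiling ``signal``.  The first matching reason
    is recorded.
    """
    if rules is None:
        rules = QcRules()

    excluded_cells = {}
    mask = ct.nondetect
    all_nd = mask.all(axis=0)
    hk_fail = (
        mask.loc[ct.housekeeping].any(axis=0)
        if (rules.require_housekeeping and ct.housekeeping)
        else pd.Series(False, index=ct.values.columns)
    )
    nd_frac = mask.mean(axis=0)
    for cell in ct.cell_ids:
        if all_nd[cell]:
            excluded_cells[cell] = "loading"
        elif hk_fail[cell]:
            excluded_cells[cell] = "failed_reaction"
        elif nd_frac[cell] > rules.max_cell_nondetect_frac:
            excluded_cells[cell] = "signal"

    kept_cells = [c for c in ct.cell_ids if c not in excluded_cells]
    if not kept_cells:
        raise ValueError("empty dataset: QC rules excluded every cell")

    excluded_genes = {}
    gene_nd_frac = mask[kept_cells].mean(axis=1)
    for gene in ct.gene_ids:
        if gene in rules.contaminated_genes:
            excluded_genes[gene] = "contamination"
        elif gene_nd_frac[gene] > rules.max_gene_nondetect_frac:
            excluded_genes[gene] = "signal"

    kept_genes = [g for g in ct.gene_ids if g not in excluded_genes]
    filtered = ct.select_cells(kept_cells).select_genes(kept_genes)

    treat = ct.treatment.loc[kept_cells]
    report = QcReport(
        excluded_cells=pd.Series(excluded_cells, dtype=object),
        excluded_genes=pd.Series(excluded_genes, dtype=object),
        retained_cells=len(kept_cells),
        retained_genes=len(kept_genes),
        retained_by_treatment=treat.value_counts().to_dict(),
    )
    assert report.retained_cells + report.n_excluded_cells == ct.n_cells
    assert report.retained_genes + report.n_excluded_genes == ct.n_genes
    return filtered, report


@dataclass
class StabilityRanking:
    """Housekeeping-candidate stability, lower M = more stable."""

    m_values: pd.Series
    ranking: list
    selected: list


def rank_housekeeping_stability(ct: CtMatrix, candidates, k: int = 3) -> StabilityRanking:
    """Rank candidate reference genes by pairwise-variation stability.

    For candidate j the measure M_j is the mean, over the other candidates k,
    of the SD across cells of the difference Ct_j - Ct_k (sample SD, ddof=1).
    A perfectly co-stable pair has constant difference, hence M = 0.  Ties
    break lexicographically on the gene label.
    """
    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("stability ranking needs at least 3 candidate genes")
    vals = ct.masked_values().loc[candidates]
    detected = vals.notna().sum(axis=1)
    thin = detected[detected < 10]
    if len(thin):
        raise ValueError(f"candidates with <10 detected cells: {list(thin.index)}")

    m = {}
    for gj in candidates:
        sds = []
        for gk in candidates:
            if gk == gj:
                continue
            diff = vals.loc[gj] - vals.loc[gk]
            sds.append(float(diff.std(ddof=1)))
        m[gj] = float(np.mean(sds))
    m_series = pd.Series(m).loc[candidates]
    ranking = sorted(candidates, key=lambda g: (m_series[g], g))
    return StabilityRanking(m_values=m_series, ranking=ranking, selected=ranking[:k])


def to_minus_dct(
    ct: CtMatrix, housekeeping=None, nondetect_policy: str = "missing"
) -> ExpressionMatrix:
    """Housekeeping-referenced expression: -dCt(g, c) = mean_h Ct(h, c) - Ct(g, c).

    Higher -dCt means more transcript.  ``nondetect_policy`` is "missing"
    (non-detects become NaN) or "floor" (non-detects keep the detection-limit
    Ct, i.e. are floor-imputed at the least-expressed observable level).
    Cells with no valid housekeeping measurement are dropped with a warning.
    """
    hk = list(housekeeping) if housekeeping is not None else list(ct.housekeeping)
    if not hk:
        raise ValueError("no housekeeping genes supplied")
    if nondetect_policy not in ("missing", "floor"):
        raise ValueError("nondetect_policy must be 'missing' or 'floor'")

    masked = ct.masked_values()
    hk_mean = masked.loc[hk].mean(axis=0, skipna=True)
    bad_cells = hk_mean.index[hk_mean.isna()].tolist()
    if bad_cells:
        warnings.warn(
            f"dropping {len(bad_cells)} cell(s) with no valid housekeeping measurement: "
            f"{bad_cells}"
        )
    keep = [c for c in ct.cell_ids if c not in bad_cells]
    source = masked if nondetect_policy == "missing" else ct.values
    vals = hk_mean[keep] - source[keep]
    return ExpressionMatrix(
        values=vals,
        stage="minus_dCt",
        provenance={
            "housekeeping": hk,
            "nondetect_policy": nondetect_policy,
            "dropped_cells": bad_cells,
        },
    )


def median_center(x: ExpressionMatrix, per_treatment=None) -> ExpressionMatrix:
    """Per-gene median centering across all retained cells -> -ddCt.

    Both treatment groups are pooled when computing the median (the default);
    pass ``per_treatment`` as a cell->treatment Series to center within
    treatments instead.  Genes with all values missing are excluded.
    """
    if x.stage != "minus_dCt":
        raise ValueError(f"median_center expects stage minus_dCt, got {x.stage}")
    vals = x.values
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"excluding all-missing genes: {vals.index[all_missing].tolist()}")
        vals = vals.loc[~all_missing]
    if per_treatment is None:
        centered = vals.sub(vals.median(axis=1, skipna=True), axis=0)
        mode = "pooled"
    else:
        centered = vals.copy()
        for t in pd.Series(per_treatment).reindex(vals.columns).unique():
            cols = [c for c in vals.columns if per_treatment[c] == t]
            centered[cols] = vals[cols].sub(vals[cols].median(axis=1, skipna=True), axis=0)
        mode = "per_treatment"
    prov = dict(x.provenance)
    prov["centering"] = mode
    return ExpressionMatrix(values=centered, stage="minus_ddCt", provenance=prov)


def modified_z(x: ExpressionMatrix) -> ExpressionMatrix:
    """Divide -ddCt by the per-gene population SD (ddof=0); unit-SD output."""
    if x.stage != "minus_ddCt":
        raise ValueError(f"modified_z expects stage minus_ddCt, got {x.stage}")
    sd = x.values.std(axis=1, ddof=0, skipna=True)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        warnings.warn(f"excluding zero-SD genes: {zero}")
    keep = [g for g in x.values.index if g not in zero]
    z = x.values.loc[keep].div(sd[keep], axis=0)
    prov = dict(x.provenance)
    prov["sd_convention"] = "population (ddof=0)"
    return ExpressionMatrix(values=z, stage="modified_z", provenance=prov)


def normalize(ct: CtMatrix, housekeeping=None, nondetect_policy="missing"):
    """Convenience: -dCt then median centering; returns the -ddCt matrix."""
    return median_center(to_minus_dct(ct, housekeeping, nondetect_policy))


def positive_call(x: ExpressionMatrix, gene: str) -> pd.Series:
    """Per-cell boolean: -ddCt strictly above zero (the per-gene median).

    Exact zero (the median itself) and non-detects classify as negative.
    """
    if x.stage != "minus_ddCt":
        raise ValueError("positive_call is defined on -ddCt values")
    if gene not in x.values.index:
        raise KeyError(f"unknown gene: {gene}")
    row = x.values.loc[gene]
    return (row > 0).fillna(False).astype(bool)


def ternary_proportions(x: ExpressionMatrix, genes) -> pd.DataFrame:
    """Compositional expression of exactly three genes, rows summing to 1.

    Only cells with strictly positive normalized expression of all three
    genes are retained (the ternary composition is undefined otherwise).
    """
    genes = list(genes)
    if len(genes) != 3:
        raise ValueError(f"ternary_proportions needs exactly 3 genes, got {len(genes)}")
    if x.stage != "minus_ddCt":
        raise ValueError("ternary_proportions is defined on -ddCt values")
    sub = x.values.loc[genes]
    ok = (sub > 0).all(axis=0) & sub.notna().all(axis=0)
    sub = sub.loc[:, ok]
    comp = sub.div(sub.sum(axis=0), axis=1)
    return comp.T  # cells x 3
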