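"""Ligand–receptor signaling-role inference between phenotype groups.

Each cell's role for a ligand–receptor pair is read off the sign quadrant of
its (-ddCt ligand, -ddCt receptor) values: paracrine source (+, <=0),
paracrine target (<=0, +), autocrine (+, +); the (-, -) quadrant plays no
dominant signaling role and is labeled "none".  Groups significantly enriched
in a role (one-sided Fisher/hypergeometric test, no multiplicity adjustment
by default) become nodes of a directed interaction network whose edges are
weighted by the fraction of each group in the mediating role.  A permutation
screen keeps only pairs whose ligand-receptor expression correlation exceeds
a shuffled-null quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._utils import rng_from_seed
from .data import ExpressionMatrix, GroupPartition
from .graph import InteractionNetwork

REGIMES = ("source", "target", "autocrine", "none")


@dataclass(frozen=True)
class LigandReceptorPair:
    ligand: str
    receptor: str

    def __post_init__(self):
        if self.ligand == self.receptor:
            raise ValueError("ligand and receptor must be distinct genes")

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class RegimeAssignment:
    """Per-cell regime for one ligand–receptor pair."""

    pair: LigandReceptorPair
    regime: pd.Series  # cell -> regime label
    missing: pd.Series  # cell -> bool, True when either gene was missing

    def counts(self) -> pd.Series:
        return self.regime.value_counts().reindex(REGIMES, fill_value=0)


def classify_regime(x: ExpressionMatrix, pair: LigandReceptorPair) -> RegimeAssignment:
    """Assign every cell to exactly one signaling regime for ``pair``.

    Cells with a missing ligand or receptor value are "none" with the missing
    flag set (they cannot be placed in a quadrant).
    """
    if x.stage != "minus_ddCt":
        raise ValueError("regime classification is defined on -ddCt values")
    for gene in (pair.ligand, pair.receptor):
        if gene not in x.values.index:
            raise KeyError(f"gene not measured: {gene}")
    lig = x.values.loc[pair.ligand]
    rec = x.values.loc[pair.receptor]
    missing = lig.isna() | rec.isna()
    regime = pd.Series("none", index=x.values.columns, dtype=object)
    regime[(lig > 0) & (rec <= 0)] = "source"
    regime[(lig <= 0) & (rec > 0)] = "target"
    regime[(lig > 0) & (rec > 0)] = "autocrine"
    regime[missing] = "none"
    return RegimeAssignment(pair=pair, regime=regime, missing=missing)


def regime_enrichment(
    assignments: list[RegimeAssignment],
    partition: GroupPartition,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Group x regime enrichment table (the package's analogue of a
    peptide-receptor signaling-role table).

    For each (pair, group, regime in {source, target, autocrine}) the 2x2
    table [group∩regime, group\\regime; nongroup∩regime, nongroup\\regime]
    is tested one-sided for over-representation via the hypergeometric tail.
    Cells with missing data for a pair are excluded from that pair's counts.
    No multiplicity adjustment by default; ``adjust="bh"`` applies
    Benjamini–Hochberg across the table.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    rows = []
    for ra in assignments:
        usable = ra.regime.index[~ra.missing]
        groups = partition.assignment.reindex(usable).dropna().astype(int)
        regime = ra.regime.loc[groups.index]
        n_total = len(groups)
        for gid in sorted(groups.unique()):
            in_group = groups == gid
            group_size = int(in_group.sum())
            if group_size == 0:
                warnings.warn(f"empty group {gid} omitted for pair {ra.pair.name}")
                continue
            for reg in ("source", "target", "autocrine"):
                in_regime = regime == reg
                k_regime = int(in_regime.sum())
                a = int((in_group & in_regime).sum())
                # one-sided over-representation tail: P(X >= a)
                p = float(hypergeom.sf(a - 1, n_total, k_regime, group_size))
                rows.append(
                    {
                        "pair": ra.pair.name,
                        "group": gid,
                        "regime": reg,
                        "fraction": a / group_size,
                        "p_value": min(p, 1.0),
                        "n_group_regime": a,
                        "n_group": group_size,
                        "n_regime": k_regime,
                        "n_total": n_total,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=[
                "pair", "group", "regime", "fraction", "p_value",
                "n_group_regime", "n_group", "n_regime", "n_total", "significant",
            ]
        )
        return table
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_adjusted"] < alpha
    elif adjust is None:
        table["significant"] = table["p_value"] < alpha
    else:
        raise ValueError("adjust must be None or 'bh'")
    table.attrs["alpha"] = alpha
    table.attrs["adjust"] = adjust
    return table


@dataclass
class ScreenResult:
    """Observed ligand–receptor correlations against permutation nulls."""

    retained: list
    observed_r: pd.Series
    null_quantile: pd.Series
    n_permutations: int
    quantile: float
    seed: int | None
    skipped: list = field(default_factory=list)


def dominant_interaction_screen(
    x: ExpressionMatrix,
    pairs: list[LigandReceptorPair],
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | None = None,
    partition: GroupPartition | None = None,
    group: int | None = None,
) -> ScreenResult:
    """Retain pairs whose ligand–receptor correlation beats the shuffled null.

    The null shuffles the receptor vector only (the minimal permutation
    destroying the association while preserving both marginals).  The
    default correlation is across all analyzed cells; pass ``partition`` and
    ``group`` to restrict to one group's cells.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly between 0 and 1")
    rng = rng_from_seed(seed)
    vals = x.values
    if group is not None:
        if partition is None:
            raise ValueError("group restriction requires a partition")
        cells = partition.members(group)
        vals = vals[cells]
    retained, skipped = [], []
    observed, null_q = {}, {}
    for pair in pairs:
        lig = vals.loc[pair.ligand]
        rec = vals.loc[pair.receptor]
        ok = lig.notna() & rec.notna()
        lv, rv = lig[ok].to_numpy(), rec[ok].to_numpy()
        if lv.size < 3 or np.std(lv) == 0 or np.std(rv) == 0:
            warnings.warn(f"skipping pair {pair.name}: constant or insufficient data")
            skipped.append(pair)
            continue
        r_obs = float(np.corrcoef(lv, rv)[0, 1])
        lc = (lv - lv.mean()) / lv.std()
        rc = (rv - rv.mean()) / rv.std()
        null = np.empty(n_perm)
        for p in range(n_perm):
            null[p] = float(lc @ rc[rng.permutation(rv.size)]) / rv.size
        q = float(np.quantile(null, quantile))
        observed[pair.name] = r_obs
        null_q[pair.name] = q
        if r_obs > q:
            retained.append(pair)
    return ScreenResult(
        retained=retained,
        observed_r=pd.Series(observed),
        null_quantile=pd.Series(null_q),
        n_permutations=n_perm,
        quantile=quantile,
        seed=seed,
        skipped=skipped,
    )


def build_interaction_network(
    enrichment: pd.DataFrame,
    screen: ScreenResult | list[LigandReceptorPair],
    partition: GroupPartition | None = None,
    alpha: float | None = None,
) -> InteractionNetwork:
    """Directed group network from enrichment flags and the screened pairs.

    For each retained pair, a directed edge runs from every group
    significantly enriched as source to every group significantly enriched as
    target; autocrine enrichment becomes a self-loop.  Edge weights are the
    source and target fractions.  Edge order is deterministic (pair name,
    then group ids).
    """
    retained = screen.retained if isinstance(screen, ScreenResult) else list(screen)
    if alpha is None:
        sig = enrichment["significant"] if "significant" in enrichment else (
            enrichment["p_value"] < 0.05
        )
    else:
        sig = enrichment["p_value"] < alpha
    net = InteractionNetwork()
    if partition is not None:
        net.group_sizes = partition.sizes().to_dict()
    for pair in sorted(retained, key=lambda p: p.name):
        sub = enrichment[(enrichment["pair"] == pair.name) & sig]
        sources = sub[sub["regime"] == "source"].sort_values("group")
        targets = sub[sub["regime"] == "target"].sort_values("group")
        autos = sub[sub["regime"] == "autocrine"].sort_values("group")
        for _, srow in sources.iterrows():
            for _, trow in targets.iterrows():
                net.add_edge(
                    srow["group"], trow["group"], pair.name,
                    srow["fraction"], trow["fraction"],
                )
        for _, arow in autos.iterrows():
            net.add_edge(
                arow["group"], arow["group"], pair.name,
                arow["fraction"], arow["fraction"],
            )
    net.edges = net.sorted_edges()
    return net
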