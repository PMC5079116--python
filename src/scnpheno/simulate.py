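"""Synthetic single-cell qPCR datasets with planted phenotype structure.

The generator produces Ct-scale data (lower Ct = more transcript) so the
whole normalization path is exercised end-to-end.  It plants the structural
features the downstream pipeline is meant to recover:

* K cell groups, each with a multi-gene signature shifted by a configurable
  number of Ct cycles;
* near-constant housekeeping genes plus a per-cell loading offset that the
  housekeeping reference removes;
* ligand–receptor expression blocks realizing paracrine source / target /
  autocrine roles per group (high = ligand/receptor shifted down in Ct, low =
  shifted up, so sign quadrants of -ddCt are recoverable);
* binary-like dropout for designated genes (a Vip-like non-detect pattern);
* spatially biased placement on a 7x7 grid (truncated discrete Gaussian per
  axis) emulating ventral/core vs dorsal/shell localization;
* a DD -> LP immediate-early-gene shift in light-pulsed cells.

Identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import rng_from_seed
from .data import CtMatrix

DEFAULT_SEED = 20161025


@dataclass(frozen=True)
class GroupSpec:
    """One planted phenotype group."""

    label: str
    proportion: float
    signature_genes: tuple
    shift_cycles: float = 3.0


@dataclass(frozen=True)
class LrPairSpec:
    """Planted ligand–receptor roles.

    The ligand is expressed high (Ct down) in the source and autocrine
    groups and low (Ct up) everywhere else; the receptor is high in the
    target and autocrine groups and low elsewhere.  Groups not named play no
    role ("none").
    """

    ligand: str
    receptor: str
    source_group: str
    target_group: str
    autocrine_groups: tuple = ()

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass(frozen=True)
class SpatialRule:
    """Truncated discrete Gaussian biases over grid indices 1..7 per axis."""

    ml_mean: float = 4.0
    vd_mean: float = 4.0
    sd: float = 1.2


@dataclass
class SyntheticConfig:
    n_cells: int = 200
    gene_ids: list = field(default_factory=list)
    housekeeping_genes: list = field(default_factory=list)
    groups: list = field(default_factory=list)  # list[GroupSpec]
    lr_pairs: list = field(default_factory=list)  # list[LrPairSpec]
    dropout: dict = field(default_factory=dict)  # gene -> {group label: prob}
    noise_sd: float = 1.0
    cell_offset_sd: Optional[float] = None  # default 0.3 * noise_sd
    housekeeping_noise_sd: Optional[float] = None  # default 0.5 * noise_sd
    detection_limit_ct: float = 40.0
    baseline_ct_range: tuple = (22.0, 30.0)
    housekeeping_ct: float = 19.0
    spatial_rules: dict = field(default_factory=dict)  # group -> SpatialRule
    n_sections: int = 6
    immediate_early_genes: list = field(default_factory=list)
    treatment_effect: float = 3.0  # Ct cycles down in LP cells
    dd_fraction: float = 0.27
    lr_shift_cycles: float = 3.0
    seed: int = DEFAULT_SEED

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")
        gene_set = set(self.gene_ids)
        referenced = set()
        for g in self.groups:
            referenced |= set(g.signature_genes)
        for p in self.lr_pairs:
            referenced |= {p.ligand, p.receptor}
        referenced |= set(self.dropout)
        referenced |= set(self.immediate_early_genes)
        unknown = referenced - gene_set
        if unknown:
            raise ValueError(f"config references genes not in the panel: {sorted(unknown)}")
        hk_with_sig = set(self.housekeeping_genes) & {
            s for g in self.groups for s in g.signature_genes
        }
        if hk_with_sig:
            raise ValueError(f"housekeeping genes carry a group signature: {sorted(hk_with_sig)}")
        group_labels = {g.label for g in self.groups}
        for p in self.lr_pairs:
            for lab in (p.source_group, p.target_group, *p.autocrine_groups):
                if lab not in group_labels:
                    raise ValueError(f"LR pair {p.name} references unknown group {lab!r}")
        for rate_map in self.dropout.values():
            for rate in rate_map.values():
                if not 0 <= rate <= 1:
                    raise ValueError("dropout probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted labels for every generated cell."""

    true_group: pd.Series  # cell -> group label
    true_regime: pd.DataFrame  # cells x pair names, regime labels
    true_coordinates: pd.DataFrame  # cells x (ml, vd, section)

    def to_json(self, path) -> None:
        payload = {
            "true_group": self.true_group.to_dict(),
            "true_regime": {c: self.true_regime.loc[c].to_dict() for c in self.true_regime.index},
            "true_coordinates": {
                c: self.true_coordinates.loc[c].astype(int).to_dict()
                for c in self.true_coordinates.index
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_config(
    n_cells: int = 200,
    noise_sd: float = 1.0,
    shift_cycles: float = 3.0,
    seed: int = DEFAULT_SEED,
) -> SyntheticConfig:
    """The frozen 4-group, 60-gene study-condition configuration.

    Four groups (proportions 0.15/0.15/0.35/0.35) with 10-gene signatures
    shifted 3 cycles, eight ligand/receptor genes realizing four
    paracrine/autocrine pairings, a Vip-like 45% dropout in the groups where
    Vip is low, DD/LP treatments with a 3-cycle immediate-early shift, and
    core/shell spatial bias for the first two groups.

    Role geometry: for every pair the ligand and the receptor are each high
    in exactly half the cells (source+autocrine and target+autocrine
    respectively), which pins the pooled median into the gap between the
    high and low expression blocks, and the autocrine fraction is 0.35 so
    the planted ligand–receptor correlation (4a - 1 under the two-level
    block model) is a detectably positive 0.4.
    """
    hk = ["Actb", "Hprt", "Atp5b"]
    sig = {
        "G1": ["Per1", "Per2", "Fos", "Jun", "Junb", "Egr2", "Grm1", "Grm5", "Grin1", "Rrad"],
        "G2": ["Cry1", "Rora", "Rorb", "Clock", "Arntl", "Dbp", "Nr1d1", "Nr1d2", "Per3", "Csnk1d"],
        "G3": ["Calb2", "Cebpb", "Npy1r", "Npy2r", "Gria4", "Creb1", "Crebbp", "Camk2a", "Six3", "Lhx1"],
        "G4": ["Gabra1", "Mapk3", "Camk2b", "Prkaca", "Pcsk1n", "Slc12a5", "Slc12a7", "Grin2b", "Gabrb3", "Syt1"],
    }
    lr_genes = ["Vip", "Vipr2", "Avp", "Avpr1b", "Adcyap1", "Adcyap1r1", "Prok2", "Prokr2"]
    iegs = ["Egr1", "Arc", "Homer1"]
    background = ["Avpr1a", "Avpr2", "Prokr1", "Ntsr1", "Oxt", "Penk"]
    genes = hk + sum(sig.values(), []) + lr_genes + iegs + background  # 60 genes
    proportions = {"G1": 0.15, "G2": 0.15, "G3": 0.35, "G4": 0.35}
    groups = [GroupSpec(lab, proportions[lab], tuple(sig[lab]), shift_cycles) for lab in sig]
    pairs = [
        LrPairSpec("Vip", "Vipr2", source_group="G1", target_group="G2", autocrine_groups=("G3",)),
        LrPairSpec("Avp", "Avpr1b", source_group="G2", target_group="G1", autocrine_groups=("G4",)),
        LrPairSpec("Adcyap1", "Adcyap1r1", source_group="G1", target_group="G2", autocrine_groups=("G4",)),
        LrPairSpec("Prok2", "Prokr2", source_group="G2", target_group="G1", autocrine_groups=("G3",)),
    ]
    spatial = {
        "G1": SpatialRule(ml_mean=5.0, vd_mean=2.0, sd=1.2),  # ventral core
        "G2": SpatialRule(ml_mean=3.0, vd_mean=6.0, sd=1.2),  # dorsal shell
        "G3": SpatialRule(ml_mean=4.0, vd_mean=4.0, sd=2.5),  # diffuse
        "G4": SpatialRule(ml_mean=4.0, vd_mean=4.0, sd=2.5),  # diffuse
    }
    return SyntheticConfig(
        n_cells=n_cells,
        gene_ids=genes,
        housekeeping_genes=hk,
        groups=groups,
        lr_pairs=pairs,
        dropout={"Vip": {"G2": 0.45, "G4": 0.45}},
        noise_sd=noise_sd,
        spatial_rules=spatial,
        immediate_early_genes=iegs,
        treatment_effect=3.0,
        dd_fraction=0.27,
        lr_shift_cycles=shift_cycles,
        seed=seed,
    )


def _group_counts(config: SyntheticConfig) -> list[int]:
    """Deterministic largest-remainder apportionment of cells to groups."""
    raw = [g.proportion * config.n_cells for g in config.groups]
    counts = [int(np.floor(r)) for r in raw]
    remainder = config.n_cells - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - np.floor(raw[i])), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _truncated_discrete_gaussian(rng, mean: float, sd: float, size: int) -> np.ndarray:
    grid = np.arange(1, 8)
    if sd <= 0:
        probs = (grid == int(round(mean))).astype(float)
    else:
        probs = np.exp(-0.5 * ((grid - mean) / sd) ** 2)
    probs = probs / probs.sum()
    return rng.choice(grid, size=size, p=probs)


def generate_dataset(config: SyntheticConfig) -> tuple[CtMatrix, GroundTruth]:
    """Draw one dataset; identical (config, seed) gives bit-identical output."""
    config.validate()
    rng = rng_from_seed(config.seed)
    n, genes = config.n_cells, list(config.gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    cell_ids = [f"cell_{i + 1:04d}" for i in range(n)]

    # group labels, shuffled so groups are not contiguous in cell order
    counts = _group_counts(config)
    labels = np.repeat([g.label for g in config.groups], counts)
    labels = labels[rng.permutation(n)]
    true_group = pd.Series(labels, index=cell_ids)

    # treatment labels, independent of group
    n_dd = int(round(config.dd_fraction * n))
    treat = np.array(["DD"] * n_dd + ["LP"] * (n - n_dd), dtype=object)
    treat = treat[rng.permutation(n)]
    treatment = pd.Series(treat, index=cell_ids)

    # per-gene baselines: evenly spaced across the panel, housekeeping fixed
    low, high = config.baseline_ct_range
    span = np.linspace(low, high, num=len(genes)) if len(genes) > 1 else np.array([low])
    baseline = np.where(
        [g in config.housekeeping_genes for g in genes], config.housekeeping_ct, span
    )

    # per-(group, gene) Ct shifts: signatures down; LR roles up/down
    shift = {g.label: np.zeros(len(genes)) for g in config.groups}
    for gspec in config.groups:
        for gene in gspec.signature_genes:
            shift[gspec.label][gene_index[gene]] -= gspec.shift_cycles
    for pair in config.lr_pairs:
        lig_high = {pair.source_group, *pair.autocrine_groups}
        rec_high = {pair.target_group, *pair.autocrine_groups}
        for gspec in config.groups:
            s = config.lr_shift_cycles
            shift[gspec.label][gene_index[pair.ligand]] += -s if gspec.label in lig_high else s
            shift[gspec.label][gene_index[pair.receptor]] += -s if gspec.label in rec_high else s

    hk_mask = np.array([g in config.housekeeping_genes for g in genes])
    noise_sd = np.where(
        hk_mask,
        config.housekeeping_noise_sd
        if config.housekeeping_noise_sd is not None
        else 0.5 * config.noise_sd,
        config.noise_sd,
    )
    offset_sd = (
        config.cell_offset_sd if config.cell_offset_sd is not None else 0.3 * config.noise_sd
    )

    ct = np.tile(baseline[:, None], (1, n)).astype(float)
    for j, cell in enumerate(cell_ids):
        ct[:, j] += shift[true_group[cell]]
    ieg_idx = [gene_index[g] for g in config.immediate_early_genes]
    lp_cols = np.flatnonzero(treat == "LP")
    for i in ieg_idx:
        ct[i, lp_cols] -= config.treatment_effect
    ct += rng.normal(0.0, 1.0, size=(1, n)) * offset_sd  # per-cell loading offset
    ct += rng.normal(0.0, 1.0, size=ct.shape) * noise_sd[:, None]

    # dropout + detection-limit censoring
    nondetect = np.zeros_like(ct, dtype=bool)
    for gene, rate_map in config.dropout.items():
        gi = gene_index[gene]
        for glabel, rate in rate_map.items():
            cols = np.flatnonzero(labels == glabel)
            hit = cols[rng.random(cols.size) < rate]
            nondetect[gi, hit] = True
    nondetect |= ct > config.detection_limit_ct
    ct = np.where(nondetect, config.detection_limit_ct, ct)

    # spatial placement
    default_rule = SpatialRule()
    ml = np.empty(n, dtype=int)
    vd = np.empty(n, dtype=int)
    for gspec in config.groups:
        rule = config.spatial_rules.get(gspec.label, default_rule)
        cols = np.flatnonzero(labels == gspec.label)
        ml[cols] = _truncated_discrete_gaussian(rng, rule.ml_mean, rule.sd, cols.size)
        vd[cols] = _truncated_discrete_gaussian(rng, rule.vd_mean, rule.sd, cols.size)
    section = rng.integers(1, config.n_sections + 1, size=n)
    coords = pd.DataFrame({"ml": ml, "vd": vd, "section": section}, index=cell_ids)

    values = pd.DataFrame(ct, index=genes, columns=cell_ids)
    mask = pd.DataFrame(nondetect, index=genes, columns=cell_ids)
    ct_matrix = CtMatrix(
        values=values,
        nondetect=mask,
        treatment=treatment,
        housekeeping=list(config.housekeeping_genes),
        coordinates=coords,
        detection_limit_ct=config.detection_limit_ct,
    )

    regime = pd.DataFrame("none", index=cell_ids, columns=[p.name for p in config.lr_pairs])
    for pair in config.lr_pairs:
        regime.loc[true_group == pair.source_group, pair.name] = "source"
        regime.loc[true_group == pair.target_group, pair.name] = "target"
        for auto in pair.autocrine_groups:
            regime.loc[true_group == auto, pair.name] = "autocrine"
    truth = GroundTruth(true_group=true_group, true_regime=regime, true_coordinates=coords)
    return ct_matrix, truth


def apply_dropout(ct: CtMatrix, gene: str, rate: float, seed) -> CtMatrix:
    """Return a copy with ~rate of the gene's cells set to non-detect."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if gene not in ct.values.index:
        raise KeyError(f"unknown gene: {gene}")
    rng = rng_from_seed(seed)
    values = ct.values.copy()
    mask = ct.nondetect.copy()
    hit = rng.random(ct.n_cells) < rate
    mask.loc[gene, hit] = True
    values.loc[gene, hit] = ct.detection_limit_ct
    return CtMatrix(
        values=values,
        nondetect=mask,
        treatment=ct.treatment.copy(),
        housekeeping=list(ct.housekeeping),
        coordinates=None if ct.coordinates is None else ct.coordinates.copy(),
        detection_limit_ct=ct.detection_limit_ct,
    )


def write_fixture(ct: CtMatrix, truth: GroundTruth, out_dir) -> dict:
    """Write the dataset as plain-text TSV/JSON fixture files.

    Layout: genes-in-rows Ct table with a header row of cell IDs, a cell
    metadata sidecar (treatment + grid indices) and a ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / "ct_values.tsv",
        "nondetect": out / "nondetect_mask.tsv",
        "metadata": out / "cell_metadata.tsv",
        "truth": out / "ground_truth.json",
    }
    ct.values.to_csv(paths["ct"], sep="\t", index_label="gene")
    ct.nondetect.astype(int).to_csv(paths["nondetect"], sep="\t", index_label="gene")
    meta = pd.DataFrame({"treatment": ct.treatment})
    if ct.coordinates is not None:
        meta = meta.join(ct.coordinates)
    meta.to_csv(paths["metadata"], sep="\t", index_label="cell")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
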