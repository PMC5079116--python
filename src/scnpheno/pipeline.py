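"""End-to-end pipeline: QC -> normalization -> networks -> communities ->
validation -> interaction inference, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .community import detect_communities, pool_residual
from .data import CtMatrix, ExpressionMatrix, GroupPartition, QcReport
from .interactions import (
    LigandReceptorPair,
    ScreenResult,
    build_interaction_network,
    classify_regime,
    dominant_interaction_screen,
    regime_enrichment,
)
from .io import read_ct_table, write_ct_table, write_graph
from .networks import (
    CELL_THRESHOLD,
    GENE_THRESHOLD,
    cell_network,
    correlation_dissimilarity,
    gene_network,
    pearson_matrix,
)
from .normalize import QcRules, median_center, modified_z, qc_filter, to_minus_dct
from .simulate import SyntheticConfig, default_config, generate_dataset
from .validate import MdsResult, PcaResult, SilhouetteResult, classical_mds, pca, silhouette

log = logging.getLogger("scnpheno.pipeline")


@dataclass
class PipelineConfig:
    """Everything a run needs; seeds are explicit, no hidden global state."""

    ct_table: Optional[str] = None  # wide TSV path; None -> synthetic data
    metadata_table: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    housekeeping: list = field(default_factory=lambda: ["Actb", "Hprt", "Atp5b"])
    qc_rules: QcRules = field(default_factory=QcRules)
    gene_threshold: float = GENE_THRESHOLD
    cell_threshold: float = CELL_THRESHOLD
    analysis_treatment: Optional[str] = "LP"  # community/interaction subset
    min_group_size: Optional[int] = None  # None -> 5% of cells
    min_degree: int = 1
    lr_pairs: list = field(
        default_factory=lambda: [
            ("Vip", "Vipr2"),
            ("Avp", "Avpr1b"),
            ("Adcyap1", "Adcyap1r1"),
            ("Prok2", "Prokr2"),
        ]
    )
    alpha: float = 0.05
    n_perm_screen: int = 1000
    screen_quantile: float = 0.95
    silhouette_space: str = "mds"  # or "expression"
    seed: int = 20161025
    out_dir: Optional[str] = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "qc_rules" in raw and isinstance(raw["qc_rules"], dict):
            raw["qc_rules"] = QcRules(**raw["qc_rules"])
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "lr_pairs" in raw:
            raw["lr_pairs"] = [tuple(p) for p in raw["lr_pairs"]]
        return cls(**raw)

    def canonical_json(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        return json.dumps(asdict(self), sort_keys=True, default=default)

    def config_hash(self) -> str:
        """Hash of the fields that determine the computed results (output
        location and log verbosity excluded)."""
        payload = json.loads(self.canonical_json())
        payload.pop("out_dir", None)
        payload.pop("verbosity", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ResultBundle:
    qc_report: QcReport
    ct: CtMatrix
    minus_dct: ExpressionMatrix
    minus_ddct: ExpressionMatrix
    z: ExpressionMatrix
    gene_graph: object
    cell_graph: object
    partition: GroupPartition
    silhouette: SilhouetteResult
    mds: MdsResult
    pca: PcaResult
    enrichment: pd.DataFrame
    screen: ScreenResult
    interaction_network: object
    manifest: dict
    ground_truth: object = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage in order; identical config+seed => identical bundle."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    stage = "input"
    try:
        if config.ct_table is not None:
            ct = read_ct_table(
                config.ct_table,
                dialect="wide",
                metadata_path=config.metadata_table,
                housekeeping=config.housekeeping,
            )
            truth = None
        else:
            syn = config.synthetic or default_config(seed=config.seed)
            ct, truth = generate_dataset(syn)
        log.info("input: %d genes x %d cells", ct.n_genes, ct.n_cells)

        stage = "qc"
        ct_f, report = qc_filter(ct, config.qc_rules)
        log.info(
            "qc: retained %d cells / %d genes (rules: %s)",
            report.retained_cells, report.retained_genes, config.qc_rules,
        )

        stage = "normalization"
        dct = to_minus_dct(ct_f, config.housekeeping)
        ddct = median_center(dct)
        z = modified_z(ddct)

        stage = "networks"
        log.info(
            "defaults in effect: gene threshold >%s (strict), cell threshold >=%s, "
            "min shared obs 10, silhouette space=%s, alpha=%s, screen quantile=%s",
            config.gene_threshold, config.cell_threshold,
            config.silhouette_space, config.alpha, config.screen_quantile,
        )
        gg = gene_network(ddct, config.gene_threshold)
        if config.analysis_treatment is not None:
            cells = [
                c for c in ddct.cell_ids if ct_f.treatment[c] == config.analysis_treatment
            ]
            if not cells:
                raise ValueError(f"no cells with treatment {config.analysis_treatment!r}")
        else:
            cells = ddct.cell_ids
        sub = ExpressionMatrix(ddct.values[cells], "minus_ddCt", dict(ddct.provenance))
        cg = cell_network(sub, config.cell_threshold)
        log.info("networks: gene graph %s, cell graph %s", gg, cg)

        stage = "communities"
        if cg.n_edges == 0:
            log.warning(
                "cell graph has no supra-threshold correlations; pooling every "
                "cell into the residual group"
            )
            partition = GroupPartition(
                assignment=pd.Series(1, index=pd.Index(cg.nodes)),
                modularity=float("nan"),
                residual_group=1,
                provenance={"method": "degenerate_empty_graph"},
            )
        else:
            raw_partition = detect_communities(cg)
            partition = pool_residual(
                cg, raw_partition, min_size=config.min_group_size, min_degree=config.min_degree
            )
        if partition.n_groups == (1 if partition.residual_group else 0):
            log.warning("all cells pooled into the residual group")
        log.info(
            "communities: %d groups (Q=%.3f), residual=%s, sizes=%s",
            partition.n_groups, partition.modularity, partition.residual_group,
            partition.sizes().to_dict(),
        )

        stage = "validation"
        ccorr = pearson_matrix(sub, "cells")
        d = correlation_dissimilarity(ccorr).fillna(2.0)
        mds = classical_mds(d, k=2)
        if config.silhouette_space == "mds":
            coords = mds.coordinates
            diffs = coords.values[:, None, :] - coords.values[None, :, :]
            dm = pd.DataFrame(
                (diffs**2).sum(axis=2) ** 0.5, index=coords.index, columns=coords.index
            )
        elif config.silhouette_space == "expression":
            dm = d
        else:
            raise ValueError("silhouette_space must be 'mds' or 'expression'")
        sil = (
            silhouette(partition.assignment, dm) if partition.n_groups > 1 else None
        )
        pca_res = pca(ddct)

        stage = "interactions"
        pairs = [LigandReceptorPair(l, r) for l, r in config.lr_pairs]
        pairs = [
            p for p in pairs
            if p.ligand in sub.values.index and p.receptor in sub.values.index
        ]
        assignments = [classify_regime(sub, p) for p in pairs]
        enrichment = regime_enrichment(assignments, partition, alpha=config.alpha)
        screen = dominant_interaction_screen(
            sub, pairs, n_perm=config.n_perm_screen,
            quantile=config.screen_quantile, seed=config.seed,
        )
        net = build_interaction_network(enrichment, screen, partition)
        log.info(
            "interactions: %d/%d pairs retained, %d directed edges",
            len(screen.retained), len(pairs), net.n_edges,
        )

        stage = "output"
        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": json.loads(config.canonical_json()),
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "files": {},
        }
        bundle = ResultBundle(
            qc_report=report, ct=ct_f, minus_dct=dct, minus_ddct=ddct, z=z,
            gene_graph=gg, cell_graph=cg, partition=partition, silhouette=sil,
            mds=mds, pca=pca_res, enrichment=enrichment, screen=screen,
            interaction_network=net, manifest=manifest, ground_truth=truth,
        )
        if config.out_dir is not None:
            _write_bundle(bundle, config)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _write_bundle(bundle: ResultBundle, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    write_ct_table(bundle.ct, out / "ct_filtered.tsv", out / "cell_metadata.tsv")
    files["ct_filtered.tsv"] = None
    files["cell_metadata.tsv"] = None
    for name, x in (("minus_dct.tsv", bundle.minus_dct), ("minus_ddct.tsv", bundle.minus_ddct),
                    ("modified_z.tsv", bundle.z)):
        x.values.to_csv(out / name, sep="\t", index_label="gene")
        files[name] = None
    bundle.qc_report.summary().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    files["qc_report.tsv"] = None
    write_graph(bundle.gene_graph, out / "gene_graph.tsv")
    write_graph(bundle.cell_graph, out / "cell_graph.tsv")
    files["gene_graph.tsv"] = None
    files["cell_graph.tsv"] = None
    part = pd.DataFrame(
        {
            "group": bundle.partition.assignment,
            "is_residual": bundle.partition.assignment == bundle.partition.residual_group,
        }
    )
    part.to_csv(out / "partition.tsv", sep="\t", index_label="cell")
    files["partition.tsv"] = None
    if bundle.silhouette is not None:
        bundle.silhouette.cluster_means.rename("mean_silhouette").to_csv(
            out / "silhouette.tsv", sep="\t", index_label="group"
        )
        files["silhouette.tsv"] = None
    bundle.mds.coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t", index_label="cell")
    files["mds_coordinates.tsv"] = None
    pd.Series(
        bundle.pca.variance_fraction, name="variance_fraction",
        index=[f"PC{i + 1}" for i in range(len(bundle.pca.variance_fraction))],
    ).to_csv(out / "pca_variance.tsv", sep="\t", index_label="component")
    files["pca_variance.tsv"] = None
    bundle.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    files["enrichment.tsv"] = None
    write_graph(bundle.interaction_network, out / "interaction_network.tsv")
    files["interaction_network.tsv"] = None

    for name in files:
        files[name] = _sha256(out / name)
    bundle.manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
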