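"""Reading and writing Ct tables, graphs and pipeline artifacts."""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CtMatrix
from .graph import Graph, InteractionNetwork

NONDETECT_TOKENS = {"", "NA", "999", "Undetermined"}


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_ct_value(token: str) -> tuple[float, bool]:
    token = token.strip()
    if token in NONDETECT_TOKENS:
        return np.nan, True
    if "," in token:
        raise ValueError(f"mixed decimal conventions: cannot parse Ct value {token!r}")
    return float(token), False


def read_ct_table(
    path,
    dialect: str = "wide",
    metadata_path=None,
    housekeeping=(),
    detection_limit_ct: float = 40.0,
    default_treatment: str = "LP",
    column_map: dict | None = None,
) -> CtMatrix:
    """Parse a Ct table from TSV/CSV.

    dialect="wide": genes in rows, header row of cell IDs, first column gene
    labels.  dialect="long": one row per (gene, cell, Ct) triple with those
    column names (remappable via ``column_map``).  Non-detect tokens
    ("", "NA", "999", "Undetermined") become non-detect mask entries.  An
    optional metadata sidecar (TSV, first column cell ID) may carry
    ``treatment`` and grid columns ``ml``/``vd``/``section``.
    """
    if dialect not in ("wide", "long"):
        raise ValueError("dialect must be 'wide' or 'long'")
    raw = _read_table(path)
    colmap = {"gene": "gene", "cell": "cell", "ct": "Ct"}
    if column_map:
        colmap.update(column_map)

    if dialect == "wide":
        # pandas silently mangles duplicate header names, so check the raw header
        with open(path) as fh:
            sep = "," if str(path).lower().endswith(".csv") else "\t"
            header = fh.readline().rstrip("\n").split(sep)
        _raise_on_duplicates(header[1:], "cell")
        gene_col = raw.columns[0]
        genes = raw[gene_col].tolist()
        cells = list(raw.columns[1:])
        _raise_on_duplicates(genes, "gene")
        vals = np.empty((len(genes), len(cells)))
        mask = np.zeros_like(vals, dtype=bool)
        for i in range(len(genes)):
            for j, c in enumerate(cells):
                vals[i, j], mask[i, j] = _parse_ct_value(raw.iloc[i][c])
    else:
        for needed in (colmap["gene"], colmap["cell"], colmap["ct"]):
            if needed not in raw.columns:
                raise ValueError(f"long dialect requires column {needed!r}")
        genes = list(dict.fromkeys(raw[colmap["gene"]]))
        cells = list(dict.fromkeys(raw[colmap["cell"]]))
        seen = set()
        vals = np.full((len(genes), len(cells)), np.nan)
        mask = np.ones_like(vals, dtype=bool)
        gi = {g: i for i, g in enumerate(genes)}
        ci = {c: j for j, c in enumerate(cells)}
        for _, row in raw.iterrows():
            key = (row[colmap["gene"]], row[colmap["cell"]])
            if key in seen:
                raise ValueError(f"duplicate (gene, cell) entry: {key}")
            seen.add(key)
            v, nd = _parse_ct_value(row[colmap["ct"]])
            vals[gi[key[0]], ci[key[1]]] = v
            mask[gi[key[0]], ci[key[1]]] = nd

    vals = np.where(np.isnan(vals) & mask, detection_limit_ct, vals)
    values = pd.DataFrame(vals, index=genes, columns=cells)
    nondetect = pd.DataFrame(mask, index=genes, columns=cells)

    treatment = pd.Series(default_treatment, index=values.columns, dtype=object)
    coordinates = None
    if metadata_path is not None:
        meta = _read_table(metadata_path)
        meta = meta.set_index(meta.columns[0])
        meta = meta.reindex(values.columns)
        if "treatment" in meta.columns:
            treatment = meta["treatment"].astype(object).rename(None)
        coord_cols = [c for c in ("ml", "vd", "section") if c in meta.columns]
        if coord_cols:
            coordinates = meta[coord_cols].apply(pd.to_numeric)
    return CtMatrix(
        values=values,
        nondetect=nondetect,
        treatment=treatment,
        housekeeping=[g for g in housekeeping if g in genes],
        coordinates=coordinates,
        detection_limit_ct=detection_limit_ct,
    )


def _raise_on_duplicates(labels, what):
    idx = pd.Index(labels)
    if idx.has_duplicates:
        raise ValueError(f"duplicate {what} labels: {idx[idx.duplicated()].unique().tolist()}")


def write_ct_table(ct: CtMatrix, path, metadata_path=None) -> None:
    """Wide-format writer; non-detects serialize as 'Undetermined'."""
    out = ct.values.astype(object).where(~ct.nondetect, "Undetermined")
    out.to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None:
        meta = pd.DataFrame({"treatment": ct.treatment})
        if ct.coordinates is not None:
            meta = meta.join(ct.coordinates)
        meta.to_csv(metadata_path, sep="\t", index_label="cell")


# ----------------------------------------------------------------- graphs
def write_graph(g: Graph | InteractionNetwork, path, format: str = "edgelist") -> None:
    """Write a graph as an edge-list TSV or GraphML.

    Edge lists carry columns (source, target, weight, annotation) in
    deterministic sorted order; directed interaction networks record the
    mediating ligand–receptor pair as the annotation and both fractions.
    """
    path = Path(path)
    if format == "edgelist":
        if isinstance(g, InteractionNetwork):
            rows = [
                (e.source, e.target, e.source_fraction, e.target_fraction, e.pair)
                for e in g.sorted_edges()
            ]
            df = pd.DataFrame(
                rows, columns=["source", "target", "source_fraction", "target_fraction", "pair"]
            )
        else:
            rows = sorted(
                ((u, v, w) for u, v, w in g.edges()), key=lambda e: (str(e[0]), str(e[1]))
            )
            df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        _write_graphml(g, path)
    else:
        raise ValueError("format must be 'edgelist' or 'graphml'")


def _write_graphml(g, path) -> None:
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    directed = isinstance(g, InteractionNetwork)
    keys = [("weight", "double")] if not directed else [
        ("source_fraction", "double"), ("target_fraction", "double"), ("pair", "string"),
    ]
    for kid, ktype in keys:
        ET.SubElement(
            root, "key", id=kid, **{"for": "edge", "attr.name": kid, "attr.type": ktype}
        )
    graph = ET.SubElement(root, "graph", edgedefault="directed" if directed else "undirected")
    if directed:
        nodes = sorted({str(e.source) for e in g.edges} | {str(e.target) for e in g.edges}
                       | {str(n) for n in g.group_sizes})
        for n in nodes:
            ET.SubElement(graph, "node", id=n)
        for e in g.sorted_edges():
            el = ET.SubElement(graph, "edge", source=str(e.source), target=str(e.target))
            for kid, val in (
                ("source_fraction", e.source_fraction),
                ("target_fraction", e.target_fraction),
                ("pair", e.pair),
            ):
                d = ET.SubElement(el, "data", key=kid)
                d.text = str(val)
    else:
        for n in g.nodes:
            ET.SubElement(graph, "node", id=str(n))
        for u, v, w in sorted(g.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            el = ET.SubElement(graph, "edge", source=str(u), target=str(v))
            d = ET.SubElement(el, "data", key="weight")
            d.text = repr(w)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_graph(path, format: str = "edgelist", directed: bool = False):
    """Read back a graph written by `write_graph` (round-trip equality)."""
    path = Path(path)
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t")
        if directed or "pair" in df.columns:
            net = InteractionNetwork()
            for _, row in df.iterrows():
                net.add_edge(
                    row["source"], row["target"], row["pair"],
                    row["source_fraction"], row["target_fraction"],
                )
            return net
        g = Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], float(row["weight"]))
        return g
    if format == "graphml":
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        root = ET.parse(path).getroot()
        graph = root.find("g:graph", ns)
        if graph.get("edgedefault") == "directed":
            net = InteractionNetwork()
            for edge in graph.findall("g:edge", ns):
                data = {d.get("key"): d.text for d in edge.findall("g:data", ns)}
                net.add_edge(
                    edge.get("source"), edge.get("target"), data["pair"],
                    float(data["source_fraction"]), float(data["target_fraction"]),
                )
            return net
        g = Graph(n.get("id") for n in graph.findall("g:node", ns))
        for edge in graph.findall("g:edge", ns):
            data = {d.get("key"): d.text for d in edge.findall("g:data", ns)}
            g.add_edge(edge.get("source"), edge.get("target"), float(data["weight"]))
        return g
    raise ValueError("format must be 'edgelist' or 'graphml'")


# ---------------------------------------------------- published study tables
STUDY_HOUSEKEEPING = ("Actb", "Hprt", "Atp5b")


def load_study_tables(data_dir, raw_name: str = "raw_ct.tsv", metadata_name: str = "cell_metadata.tsv") -> CtMatrix:
    """Load the study's supplementary raw-Ct tables from a local directory.

    Expects a wide genes-x-cells TSV of raw Ct values plus a metadata sidecar
    with per-cell treatment (DD/LP) and optional grid coordinates.  These
    files are the published supplementary data and must be supplied by the
    user; they do not ship with the package.
    """
    data_dir = Path(data_dir)
    raw = data_dir / raw_name
    meta = data_dir / metadata_name
    if not raw.exists():
        raise FileNotFoundError(
            f"supplementary raw-Ct table not found at {raw}; place the published "
            "supplementary text files there to run the study-data analyses"
        )
    return read_ct_table(
        raw,
        dialect="wide",
        metadata_path=meta if meta.exists() else None,
        housekeeping=STUDY_HOUSEKEEPING,
    )
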