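"""Pathway-centered interaction networks with PCC-scored edges.

Nodes are the genes of a metabolic pathway (e.g. starch biosynthesis
and degradation) plus their interaction partners; pathway genes with no
recorded interaction are retained as isolated nodes.  Each undirected
edge carries the interolog confidence value it was imported with and,
where expression covers both endpoints, the Pearson correlation (PCC)
of the two genes' log2 profiles, flagged ``high_pcc`` above a threshold
(default 0.5).  Directed regulator edges (bound / direct_target /
regulated_up / regulated_down relations of a transcription factor such
as OsbZIP23) are overlaid on top.  Export targets are SIF plus node and
edge attribute TSVs for Cytoscape, and GraphML for lossless round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Collection, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .expression import ExpressionMatrix

REGULATOR_RELATIONS = ("bound", "direct_target", "regulated_up", "regulated_down")

# SIF edge-type vocabulary
_SIF_TYPES = {
    "interaction": "interacts",
    "bound": "bound",
    "direct_target": "targets",
    "regulated_up": "regulates_up",
    "regulated_down": "regulates_down",
}


def pearson(x: Iterable[float], y: Iterable[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class InteractionNetwork:
    """Undirected confidence/PCC edges plus directed regulator overlays."""

    graph: nx.Graph
    regulator_edges: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(
            columns=["regulator", "target", "relation"]
        )
    )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = [{"gene_id": n, **attrs} for n, attrs in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, **attrs}
            for a, b, attrs in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows)


def read_interactions(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b", "confidence"} <= set(table.columns):
        raise FormatError("interaction TSV needs gene_a, gene_b, confidence")
    return table


def validate_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops, deduplicate unordered pairs, check confidences."""
    conf = table["confidence"].astype(float)
    if ((conf <= 0) | (conf > 1)).any():
        bad = table.loc[(conf <= 0) | (conf > 1)].head()
        raise ValidationError(f"confidence values outside (0, 1]:\n{bad}")
    table = table[table["gene_a"] != table["gene_b"]].copy()
    key = table.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    table = table.loc[~key.duplicated()].reset_index(drop=True)
    return table


def build_network(
    pathway_genes: Collection[str],
    interactions: pd.DataFrame,
    expression: ExpressionMatrix | None = None,
    labels: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    pcc_threshold: float = 0.5,
    characterized: Collection[str] = (),
    functional_bins: dict[str, str] | None = None,
    drop_low_pcc: bool = False,
) -> InteractionNetwork:
    """Assemble the pathway network.

    Node set = pathway genes (kept even when isolated) plus every
    interaction partner.  Per-edge PCC is computed over the expression
    matrix columns where both endpoints are covered; otherwise the edge
    carries no pcc and is never ``high_pcc``.  Drought class and diurnal
    flags are joined from the label/call tables when given.
    """
    pathway = list(dict.fromkeys(pathway_genes))
    if not pathway:
        raise ValueError("empty pathway gene list")
    clean = validate_interactions(interactions)

    if expression is not None and expression.scale != "log2":
        raise ValidationError("expression for PCC must be log2-scaled")

    label_map = (
        labels.set_index("gene_id")["drought_class"].to_dict() if labels is not None else {}
    )
    diurnal_map = (
        calls.set_index("gene_id")["rhythmic"].to_dict() if calls is not None else {}
    )
    bins = functional_bins or {}
    charset = set(characterized)

    g = nx.Graph()
    for gene in pathway:
        g.add_node(gene)
    for row in clean.itertuples():
        g.add_node(row.gene_a)
        g.add_node(row.gene_b)
        pcc = None
        if expression is not None:
            v = expression.values
            if row.gene_a in v.index and row.gene_b in v.index:
                a = v.loc[row.gene_a].to_numpy()
                b = v.loc[row.gene_b].to_numpy()
                if a.std() > 0 and b.std() > 0:
                    pcc = pearson(a, b)
        attrs = {"confidence": float(row.confidence)}
        if pcc is not None:
            attrs["pcc"] = pcc
            attrs["high_pcc"] = bool(pcc > pcc_threshold)
        else:
            attrs["high_pcc"] = False
        if drop_low_pcc and not attrs["high_pcc"]:
            continue
        g.add_edge(row.gene_a, row.gene_b, **attrs)

    for node in g.nodes:
        g.nodes[node]["in_pathway"] = node in set(pathway)
        g.nodes[node]["drought_class"] = label_map.get(node, "none")
        g.nodes[node]["diurnal"] = bool(diurnal_map.get(node, False))
        g.nodes[node]["characterized"] = node in charset
        if node in bins:
            g.nodes[node]["functional_bin"] = bins[node]
    return InteractionNetwork(graph=g)


def overlay_regulator(
    network: InteractionNetwork, regulator_table: pd.DataFrame
) -> InteractionNetwork:
    """Append directed regulator edges; unknown relation strings are errors.

    Targets (or regulators) absent from the network are added as nodes.
    Duplicate (regulator, target, relation) records are collapsed.
    """
    req = {"regulator", "target", "relation"}
    if not req <= set(regulator_table.columns):
        raise FormatError(f"regulator table needs columns {sorted(req)}")
    bad = set(regulator_table["relation"]) - set(REGULATOR_RELATIONS)
    if bad:
        raise FormatError(
            f"unknown regulator relation(s) {sorted(bad)}; "
            f"allowed: {REGULATOR_RELATIONS}"
        )
    dedup = regulator_table.drop_duplicates(["regulator", "target", "relation"])
    g = network.graph.copy()
    for row in dedup.itertuples():
        for node in (row.regulator, row.target):
            if node not in g:
                g.add_node(
                    node,
                    in_pathway=False,
                    drought_class="none",
                    diurnal=False,
                    characterized=False,
                )
    merged = (
        pd.concat([network.regulator_edges, dedup[["regulator", "target", "relation"]]])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return InteractionNetwork(graph=g, regulator_edges=merged)


def export_network(
    network: InteractionNetwork, out_dir: str | Path, fmt: str = "SIF"
) -> dict[str, Path]:
    """Write the network as SIF + attribute TSVs or as GraphML.

    SIF: one ``gene_a<TAB>interacts<TAB>gene_b`` line per undirected
    edge, regulator edges typed by relation; node and edge attributes go
    to companion TSVs.  GraphML embeds all attributes and round-trips
    losslessly through :func:`read_graphml_network`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if fmt.upper() == "SIF":
        sif = out_dir / "network.sif"
        with open(sif, "w") as fh:
            for a, b in sorted(network.graph.edges()):
                fh.write(f"{a}\t{_SIF_TYPES['interaction']}\t{b}\n")
            for row in network.regulator_edges.itertuples():
                fh.write(f"{row.regulator}\t{_SIF_TYPES[row.relation]}\t{row.target}\n")
        written["sif"] = sif
        nodes = out_dir / "node_attributes.tsv"
        network.node_table().to_csv(nodes, sep="\t", index=False, na_rep="NA")
        written["node_attributes"] = nodes
        edges = out_dir / "edge_attributes.tsv"
        network.edge_table().to_csv(edges, sep="\t", index=False, na_rep="NA")
        written["edge_attributes"] = edges
    elif fmt.upper() == "GRAPHML":
        path = out_dir / "network.graphml"
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(network.graph.nodes(data=True)))
        for a, b, attrs in sorted(network.graph.edges(data=True)):
            g.add_edge(a, b, edge_kind="interaction", **attrs)
        for row in network.regulator_edges.sort_values(
            ["regulator", "target", "relation"]
        ).itertuples():
            g.add_edge(row.regulator, row.target, edge_kind=row.relation)
        nx.write_graphml(g, path)
        written["graphml"] = path
    else:
        raise ValueError(f"unknown export format {fmt!r}; use SIF or GraphML")
    return written


def read_graphml_network(path: str | Path) -> InteractionNetwork:
    """Inverse of GraphML export."""
    g = nx.read_graphml(path, force_multigraph=True)
    und = nx.Graph()
    und.add_nodes_from(g.nodes(data=True))
    reg_rows = []
    for a, b, attrs in g.edges(data=True):
        kind = attrs.pop("edge_kind", "interaction")
        if kind == "interaction":
            und.add_edge(a, b, **attrs)
        else:
            reg_rows.append({"regulator": a, "target": b, "relation": kind})
    reg = pd.DataFrame(reg_rows, columns=["regulator", "target", "relation"])
    return InteractionNetwork(graph=und, regulator_edges=reg)
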