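"""Bipartite drug-gene network assembly and export.

Drug nodes and gene nodes are joined only by retained drug-gene
correlation records; the edge weight is the (signed) Pearson r and the
Holm-adjusted p-value rides along as an edge attribute. Gene nodes carry a
functional category (oncogene / tsg / fusion / other); genes missing from
the annotation table default to "other". Nodes with zero retained edges do
not enter the network.

Node attributes: ``node_type`` ("drug" | "gene"), ``bipartite`` (0 | 1),
``category`` (genes only). Edge attributes: ``weight`` (Pearson r),
``holm_p``. These names are stable across the GraphML round-trip.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "GENE_CATEGORIES",
    "build_network",
    "degree_summary",
    "extract_subnetwork",
    "read_annotations",
    "read_graphml",
    "target_sets",
    "write_edge_tsv",
    "write_graphml",
    "write_sif",
]

GENE_CATEGORIES = ("oncogene", "tsg", "fusion", "other")


def read_annotations(path) -> dict[str, str]:
    """Gene -> category table (TSV with columns gene_id, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        cat = row.category.lower()
        if cat not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {row.category!r} for {row.gene_id}")
        out[row.gene_id] = cat
    return out


def build_network(
    records: pd.DataFrame,
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Bipartite graph from retained correlation records.

    ``records`` must already be filtered; duplicate (drug, gene) rows
    raise. Node sets are exactly the ids appearing in the records, so
    every node has degree >= 1 by construction.
    """
    annotations = dict(annotations or {})
    for cat in annotations.values():
        if cat not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {cat!r}")
    if records.duplicated(subset=["drug_id", "gene_id"]).any():
        dups = records[records.duplicated(subset=["drug_id", "gene_id"])]
        raise ValueError(
            f"duplicate drug-gene records: {dups[['drug_id', 'gene_id']].values[:3]}"
        )
    overlap = set(records["drug_id"]) & set(records["gene_id"])
    if overlap:
        raise ValueError(f"ids used both as drug and gene: {sorted(overlap)[:5]}")

    g = nx.Graph()
    for row in records.itertuples(index=False):
        if row.drug_id not in g:
            g.add_node(row.drug_id, node_type="drug", bipartite=0)
        if row.gene_id not in g:
            g.add_node(
                row.gene_id, node_type="gene", bipartite=1,
                category=annotations.get(row.gene_id, "other"),
            )
        g.add_edge(
            row.drug_id, row.gene_id,
            weight=float(row.pearson_r), holm_p=float(row.holm_p),
        )
    assert_bipartite(g)
    return g


def assert_bipartite(g: nx.Graph) -> None:
    """Structural check: every edge joins one drug node and one gene node."""
    for u, v in g.edges():
        tu, tv = g.nodes[u].get("node_type"), g.nodes[v].get("node_type")
        if {tu, tv} != {"drug", "gene"}:
            raise ValueError(f"edge {u!r}-{v!r} violates bipartiteness ({tu}, {tv})")


def drug_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("node_type") == "drug")


def gene_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("node_type") == "gene")


def target_sets(g: nx.Graph) -> dict[str, set[str]]:
    """Per-drug target sets: each drug maps to its gene neighborhood."""
    return {d: set(g.neighbors(d)) for d in drug_nodes(g)}


def extract_subnetwork(g: nx.Graph, drugs: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the chosen drugs and all their gene neighbors."""
    drugs = set(drugs)
    known = set(drug_nodes(g))
    unknown = drugs - known
    if unknown:
        raise ValueError(f"unknown drug ids: {sorted(unknown)}")
    genes: set[str] = set()
    for d in drugs:
        genes |= set(g.neighbors(d))
    sub = g.subgraph(drugs | genes).copy()
    assert_bipartite(sub)
    return sub


def degree_summary(g: nx.Graph) -> pd.DataFrame:
    """Table (node, type, degree); drug and gene degree totals both equal |E|."""
    rows = [
        (n, d.get("node_type"), g.degree(n))
        for n, d in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["node", "type", "degree"])


# ---------------------------------------------------------------------------
# exports

def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    assert_bipartite(g)
    return g


def write_sif(g: nx.Graph, path) -> None:
    """SIF export: one ``drug<TAB>targets<TAB>gene`` line per edge."""
    with open(path, "w") as fh:
        for d in drug_nodes(g):
            for ggene in sorted(g.neighbors(d)):
                fh.write(f"{d}\ttargets\t{ggene}\n")


def write_edge_tsv(g: nx.Graph, path) -> None:
    rows = [
        (d, gg, g.edges[d, gg]["weight"], g.edges[d, gg]["holm_p"],
         g.nodes[gg].get("category", "other"))
        for d in drug_nodes(g)
        for gg in sorted(g.neighbors(d))
    ]
    pd.DataFrame(
        rows, columns=["drug_id", "gene_id", "pearson_r", "holm_p", "gene_category"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
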