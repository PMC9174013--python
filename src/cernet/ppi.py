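"""Confidence-filtered protein-protein interaction graph and hub genes.

Edges below the confidence threshold (strict >, default 0.4) or touching
genes outside the whitelist are discarded; hub genes are the nodes whose
degree in the retained graph meets a minimum (default 2), ranked by degree
descending with lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .assembly import CeRNANetwork

__all__ = ["HubRecord", "build_graph", "hub_genes", "hub_subnetwork", "read_ppi_edges"]


@dataclass(frozen=True)
class HubRecord:
    gene_id: str
    degree: int


def build_graph(
    edges: pd.DataFrame,
    gene_whitelist=None,
    min_confidence: float = 0.4,
) -> nx.Graph:
    """Build an undirected PPI graph from a scored edge table.

    ``edges`` has columns gene_a, gene_b, confidence.  Self-loops are
    dropped; duplicate edges collapse keeping the maximum confidence;
    retained edges have both endpoints whitelisted (when a whitelist is
    given) and confidence strictly above ``min_confidence``.
    """
    conf = pd.to_numeric(edges["confidence"], errors="raise")
    if ((conf < 0) | (conf > 1)).any() or conf.isna().any():
        raise ValueError("confidence scores must lie in [0, 1]")
    g = nx.Graph()
    if gene_whitelist is not None:
        gene_whitelist = set(gene_whitelist)
        g.add_nodes_from(gene_whitelist)
    for gene_a, gene_b, c in zip(edges["gene_a"], edges["gene_b"], conf):
        if gene_a == gene_b:
            continue
        if gene_whitelist is not None and (
            gene_a not in gene_whitelist or gene_b not in gene_whitelist
        ):
            continue
        prev = g.get_edge_data(gene_a, gene_b)
        if prev is None or c > prev["confidence"]:
            g.add_edge(gene_a, gene_b, confidence=float(c))
    # apply the strict confidence filter after duplicate collapsing
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["confidence"] <= min_confidence]
    g.remove_edges_from(drop)
    return g


def hub_genes(graph: nx.Graph, min_degree: int = 2) -> list[HubRecord]:
    """Nodes with degree >= min_degree, ranked by degree desc then id."""
    records = [HubRecord(gene, d) for gene, d in graph.degree() if d >= min_degree]
    return sorted(records, key=lambda r: (-r.degree, r.gene_id))


def hub_subnetwork(network: CeRNANetwork, hubs) -> CeRNANetwork:
    """Restrict a ceRNA network to the triads whose mRNA is a hub gene."""
    hubs = set(hubs)
    sub = CeRNANetwork()
    for t in network.triads:
        if t.mrna_id not in hubs:
            continue
        sub.triads.append(t)
        for nid in (t.circ_id, t.mirna_id, t.mrna_id):
            sub.nodes[nid] = network.nodes[nid]
        sub.edges.add((t.circ_id, t.mirna_id, "circRNA-miRNA"))
        sub.edges.add((t.mirna_id, t.mrna_id, "miRNA-mRNA"))
    sub.triads.sort()
    return sub


def read_ppi_edges(path) -> pd.DataFrame:
    """PPI TSV: gene_a, gene_b, confidence."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
    return df


def write_hub_table(hubs: list[HubRecord], path) -> None:
    pd.DataFrame([(h.gene_id, h.degree) for h in hubs], columns=["gene", "degree"]).to_csv(
        path, sep="\t", index=False
    )
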