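"""Assembly of the circRNA-miRNA-mRNA ceRNA network.

Under the sponge hypothesis a circRNA competes with mRNAs for shared
miRNA binding sites, so a direction-consistent triad follows one of two
paradigms: an upregulated circRNA sequesters a downregulated miRNA whose
mRNA target is derepressed (up-down-up), or the mirror case
(down-up-down).  ``assemble`` joins the two pair catalogs on shared
miRNAs, crosschecks every member against its differential-expression
direction, and keeps exactly the paradigm-consistent triads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .interactions import InteractionPair, normalize_mirna_id

__all__ = ["Triad", "CeRNANetwork", "assemble", "summarize", "export_network", "read_network"]

UP_DOWN_UP = "up-down-up"
DOWN_UP_DOWN = "down-up-down"


@dataclass(frozen=True, order=True)
class Triad:
    circ_id: str
    mirna_id: str
    mrna_id: str
    paradigm: str


@dataclass
class CeRNANetwork:
    """Typed nodes, edges and direction-labelled triads.

    nodes: id -> (type, direction); edges: set of (source, target,
    type-pair); triads: lexicographically sorted, duplicate-free.
    """

    nodes: dict[str, tuple[str, str]] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    triads: list[Triad] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CeRNANetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and sorted(self.triads) == sorted(other.triads)
        )

    @property
    def mrna_ids(self) -> set[str]:
        return {nid for nid, (ntype, _) in self.nodes.items() if ntype == "mRNA"}


def _check_directions(direction_map: dict[str, str], label: str) -> dict[str, str]:
    clean = {}
    for fid, direction in direction_map.items():
        if direction not in ("up", "down"):
            raise ValueError(f"{label}: direction for {fid} must be up or down, got {direction!r}")
        clean[fid] = direction
    return clean


def _paradigm(circ_dir: str, mirna_dir: str, mrna_dir: str) -> str | None:
    if (circ_dir, mirna_dir, mrna_dir) == ("up", "down", "up"):
        return UP_DOWN_UP
    if (circ_dir, mirna_dir, mrna_dir) == ("down", "up", "down"):
        return DOWN_UP_DOWN
    return None


def assemble(
    circ_mirna: list[InteractionPair],
    mirna_mrna: list[InteractionPair],
    circ_de: dict[str, str],
    mirna_de: dict[str, str],
    mrna_de: dict[str, str],
) -> CeRNANetwork:
    """Join the pair catalogs on shared miRNAs and keep paradigm-consistent triads.

    Direction maps hold up/down entries only (non-significant features are
    simply absent).  miRNA ids are canonicalized on both the catalogs and
    the direction map so spelling variants match.  Output ordering is
    deterministic (lexicographic by circ, miRNA, mRNA id).
    """
    circ_de = _check_directions(circ_de, "circRNA directions")
    mrna_de = _check_directions(mrna_de, "mRNA directions")
    mirna_norm: dict[str, str] = {}
    for mid, direction in _check_directions(mirna_de, "miRNA directions").items():
        key = normalize_mirna_id(mid)
        if mirna_norm.get(key, direction) != direction:
            raise ValueError(f"miRNA {mid} appears with inconsistent directions")
        mirna_norm[key] = direction

    targets_by_mirna: dict[str, set[str]] = {}
    for p in mirna_mrna:
        if (p.source_type, p.target_type) != ("miRNA", "mRNA"):
            raise ValueError("second catalog must hold miRNA->mRNA pairs")
        targets_by_mirna.setdefault(normalize_mirna_id(p.source_id), set()).add(p.target_id)

    triads: set[Triad] = set()
    for p in circ_mirna:
        if (p.source_type, p.target_type) != ("circRNA", "miRNA"):
            raise ValueError("first catalog must hold circRNA->miRNA pairs")
        c, m = p.source_id, normalize_mirna_id(p.target_id)
        if c not in circ_de or m not in mirna_norm:
            continue
        for g in targets_by_mirna.get(m, ()):
            if g not in mrna_de:
                continue
            paradigm = _paradigm(circ_de[c], mirna_norm[m], mrna_de[g])
            if paradigm is not None:
                triads.add(Triad(c, m, g, paradigm))

    net = CeRNANetwork()
    for t in sorted(triads):
        net.nodes[t.circ_id] = ("circRNA", circ_de[t.circ_id])
        net.nodes[t.mirna_id] = ("miRNA", mirna_norm[t.mirna_id])
        net.nodes[t.mrna_id] = ("mRNA", mrna_de[t.mrna_id])
        net.edges.add((t.circ_id, t.mirna_id, "circRNA-miRNA"))
        net.edges.add((t.mirna_id, t.mrna_id, "miRNA-mRNA"))
        net.triads.append(t)
    return net


def summarize(network: CeRNANetwork) -> dict:
    """Distinct node counts per type, triad count, and paradigm breakdown."""
    by_type = {"circRNA": 0, "miRNA": 0, "mRNA": 0}
    for ntype, _ in network.nodes.values():
        by_type[ntype] += 1
    per_paradigm = {UP_DOWN_UP: 0, DOWN_UP_DOWN: 0}
    for t in network.triads:
        per_paradigm[t.paradigm] += 1
    return {
        "n_circ": by_type["circRNA"],
        "n_mirna": by_type["miRNA"],
        "n_mrna": by_type["mRNA"],
        "n_triads": len(network.triads),
        "n_per_paradigm": per_paradigm,
    }


def export_network(network: CeRNANetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML (typed/directed attributes) or a triad TSV."""
    if format == "graphml":
        g = nx.DiGraph()
        for nid in sorted(network.nodes):
            ntype, direction = network.nodes[nid]
            g.add_node(nid, type=ntype, direction=direction)
        for source, target, type_pair in sorted(network.edges):
            g.add_edge(source, target, type_pair=type_pair)
        g.graph["triads"] = ";".join(
            f"{t.circ_id},{t.mirna_id},{t.mrna_id},{t.paradigm}" for t in network.triads
        )
        nx.write_graphml(g, path)
    elif format == "tsv":
        pd.DataFrame(
            [(t.circ_id, t.mirna_id, t.mrna_id, t.paradigm) for t in network.triads],
            columns=["circRNA", "miRNA", "mRNA", "paradigm"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path, format: str = "graphml") -> CeRNANetwork:
    """Round-trip reader for :func:`export_network` output."""
    net = CeRNANetwork()
    if format == "graphml":
        g = nx.read_graphml(path)
        for nid, attrs in g.nodes(data=True):
            net.nodes[nid] = (attrs["type"], attrs["direction"])
        for source, target, attrs in g.edges(data=True):
            net.edges.add((source, target, attrs["type_pair"]))
        spec = g.graph.get("triads", "")
        if spec:
            for chunk in spec.split(";"):
                c, m, mr, paradigm = chunk.split(",")
                net.triads.append(Triad(c, m, mr, paradigm))
        net.triads.sort()
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            t = Triad(row.circRNA, row.miRNA, row.mRNA, row.paradigm)
            net.triads.append(t)
            circ_dir, mirna_dir, mrna_dir = (
                ("up", "down", "up") if t.paradigm == UP_DOWN_UP else ("down", "up", "down")
            )
            net.nodes[t.circ_id] = ("circRNA", circ_dir)
            net.nodes[t.mirna_id] = ("miRNA", mirna_dir)
            net.nodes[t.mrna_id] = ("mRNA", mrna_dir)
            net.edges.add((t.circ_id, t.mirna_id, "circRNA-miRNA"))
            net.edges.add((t.mirna_id, t.mrna_id, "miRNA-mRNA"))
        net.triads.sort()
    else:
        raise ValueError(f"unknown format {format!r}")
    return net
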