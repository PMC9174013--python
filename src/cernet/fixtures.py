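"""Packaged worked-example tables and their parsers.

Three small TSV tables ship with the package: the characteristics of the
11 intersected circRNAs (genomic position, strand, host gene, regulation),
the 16 hub genes with their PPI degrees, and the circRNA-miRNA-hub-gene
subnetwork rows.  They are stored verbatim as printed (including the
"has-" spelling of the miRNA species prefix, which the loaders normalize)
and drive worked-example tests and the CLI's fixture mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .interactions import merge_pairs, normalize_mirna_id

__all__ = [
    "CircRecord",
    "parse_position",
    "load_table1",
    "load_table2",
    "load_table3",
    "fixture_path",
]

_POSITION_RE = re.compile(r"^(chr[0-9XYM]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class CircRecord:
    circ_id: str
    chrom: str
    start: int
    end: int
    genomic_length: int
    strand: str
    transcript: str
    gene_symbol: str
    regulation: str  # up / down


def parse_position(position: str) -> tuple[str, int, int]:
    """Parse "chr12:27867712-27877119" into (chrom, start, end), end > start."""
    m = _POSITION_RE.match(position.strip())
    if m is None:
        raise ValueError(f"malformed position string: {position!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if end <= start:
        raise ValueError(f"end must exceed start in position {position!r}")
    return chrom, start, end


def fixture_path(name: str):
    """Path to a packaged fixture: table1, table2 or table3."""
    if name not in ("table1", "table2", "table3"):
        raise ValueError(f"unknown fixture {name!r}")
    return resources.files("cernet.data").joinpath(f"{name}.tsv")


def load_table1() -> list[CircRecord]:
    """The 11 intersected circRNAs; genomic_length derived as end - start."""
    df = pd.read_csv(fixture_path("table1"), sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        chrom, start, end = parse_position(row.Position)
        records.append(
            CircRecord(
                circ_id=row.circRNA_ID,
                chrom=chrom,
                start=start,
                end=end,
                genomic_length=end - start,
                strand=row.Strand,
                transcript=row.Best_transcript,
                gene_symbol=row.Gene_symbol,
                regulation=row.Regulation.lower(),
            )
        )
    return records


def load_table2() -> pd.DataFrame:
    """Hub genes with their PPI interaction degree (the Freq column)."""
    df = pd.read_csv(fixture_path("table2"), sep="\t", dtype={"Freq": int})
    return df.rename(columns={"String_node": "gene", "Freq": "degree"})[["gene", "degree"]]


def load_table3():
    """Decompose the printed subnetwork into edge lists and a triad list.

    Returns (circ-miRNA pairs, miRNA-gene pairs, triad rows); miRNA ids are
    normalized (the printed "has-" prefix maps to the canonical form) and
    edges are unique; triad rows keep the printed order.
    """
    df = pd.read_csv(fixture_path("table3"), sep="\t", dtype=str)
    triads = [
        (row.DEcircRNA, normalize_mirna_id(row.DEmiRNA), row.DEmRNA)
        for row in df.itertuples(index=False)
    ]
    circ_mirna = merge_pairs(
        {(c, m, "subnetwork") for c, m, _ in triads}, "circRNA", "miRNA"
    )
    mirna_mrna = merge_pairs(
        {(m, g, "subnetwork") for _, m, g in triads}, "miRNA", "mRNA"
    )
    return circ_mirna, mirna_mrna, triads
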