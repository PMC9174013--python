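"""Interaction-pair catalogs and the multi-database consensus filter.

Pair tables replace live queries to target-prediction resources: one row
per (source, target, database) attestation.  Rows for the same pair are
merged with their database sets unioned, and miRNA-to-mRNA pairs can be
filtered to those supported by at least ``min_databases`` databases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "InteractionPair",
    "normalize_mirna_id",
    "load_pairs",
    "merge_pairs",
    "consensus_filter",
    "write_pairs",
]

ALLOWED_TYPE_PAIRS = {("circRNA", "miRNA"), ("miRNA", "mRNA")}


@dataclass(frozen=True)
class InteractionPair:
    """A typed source->target interaction with database provenance."""

    source_id: str
    target_id: str
    source_type: str
    target_type: str
    databases: frozenset[str]

    def __post_init__(self) -> None:
        if (self.source_type, self.target_type) not in ALLOWED_TYPE_PAIRS:
            raise ValueError(
                f"disallowed type combination {self.source_type}->{self.target_type}"
            )
        if not self.databases:
            raise ValueError("databases must be non-empty")


def normalize_mirna_id(mirna: str) -> str:
    """Canonicalize a miRNA label for matching across catalogs.

    Case-folds and strips a species prefix; the common "has-" misspelling
    of "hsa-" is treated as the same prefix.
    """
    m = mirna.strip().casefold()
    for prefix in ("hsa-", "has-"):
        if m.startswith(prefix):
            m = m[len(prefix):]
            break
    return m


def _maybe_normalize(feature_id: str, feature_type: str) -> str:
    return normalize_mirna_id(feature_id) if feature_type == "miRNA" else feature_id.strip()


def merge_pairs(rows, source_type: str, target_type: str) -> list[InteractionPair]:
    """Merge (source, target, database) rows into unique pairs.

    Deterministic: output sorted by (source, target) regardless of row order.
    """
    if (source_type, target_type) not in ALLOWED_TYPE_PAIRS:
        raise ValueError(f"disallowed type combination {source_type}->{target_type}")
    merged: dict[tuple[str, str], set[str]] = {}
    for source, target, database in rows:
        key = (_maybe_normalize(source, source_type), _maybe_normalize(target, target_type))
        merged.setdefault(key, set()).add(str(database).strip())
    return [
        InteractionPair(s, t, source_type, target_type, frozenset(dbs))
        for (s, t), dbs in sorted(merged.items())
    ]


def load_pairs(path, source_type: str, target_type: str) -> list[InteractionPair]:
    """Read a pair TSV (columns source_id, target_id, database) and merge.

    Malformed rows (missing fields) are reported with their line numbers.
    """
    if (source_type, target_type) not in ALLOWED_TYPE_PAIRS:
        raise ValueError(f"disallowed type combination {source_type}->{target_type}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_id", "target_id", "database"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = df.index[df[list(required)].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:20])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    rows = df[["source_id", "target_id", "database"]].itertuples(index=False, name=None)
    return merge_pairs(rows, source_type, target_type)


def consensus_filter(pairs: list[InteractionPair], min_databases: int = 1) -> list[InteractionPair]:
    """Keep miRNA->mRNA pairs attested by at least ``min_databases`` databases."""
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    for p in pairs:
        if (p.source_type, p.target_type) != ("miRNA", "mRNA"):
            raise ValueError("consensus filter applies to miRNA->mRNA pairs only")
    known = set().union(*(p.databases for p in pairs)) if pairs else set()
    if pairs and min_databases > len(known):
        warnings.warn(
            f"min_databases={min_databases} exceeds the {len(known)} databases present",
            stacklevel=2,
        )
    return [p for p in pairs if len(p.databases) >= min_databases]


def write_pairs(pairs: list[InteractionPair], path) -> None:
    """One row per (pair, database) attestation, sorted for stable diffs."""
    rows = [
        (p.source_id, p.target_id, db)
        for p in sorted(pairs, key=lambda p: (p.source_id, p.target_id))
        for db in sorted(p.databases)
    ]
    pd.DataFrame(rows, columns=["source_id", "target_id", "database"]).to_csv(
        path, sep="\t", index=False
    )
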