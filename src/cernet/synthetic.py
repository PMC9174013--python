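"""Seeded synthetic studies with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: two
paired tumor/normal circRNA expression datasets (so the cross-dataset
intersection has real work), one miRNA and one mRNA study, planted
direction-consistent circRNA-miRNA-mRNA triads following the two sponge
paradigms (up-down-up and down-up-down), interaction catalogs mixing the
true pairs with direction-agnostic decoys attributed to pseudo-databases, a
PPI edge table with a planted high-confidence hub clique, annotation term
sets enriched for the planted genes, and a Ct table encoding the planted
circRNA fold changes through the ddCt model.

Expression model, per feature on the log2 scale:

    x = baseline + condition_shift + pair_effect + noise

with baseline ~ Normal(8, 2) drawn once per feature, condition_shift =
+/- effect_lfc on tumor samples of planted DE features (sign per planted
direction, zero otherwise), pair_effect ~ Normal(0, 0.5 * noise_sd) shared
by the two samples of a pair, and noise ~ Normal(0, noise_sd) per cell.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .assembly import Triad, UP_DOWN_UP, DOWN_UP_DOWN
from .diffexpr import ExpressionStudy
from .enrichment import AnnotationCollection
from .interactions import InteractionPair, merge_pairs

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticStudy", "generate_study"]

CIRC_DB = "circdb"  # single catalog backing circRNA-miRNA pairs


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults reflect a small paired tumor/normal design: 10 sample pairs
    per expression dataset, 30% of features differentially expressed with a
    planted |log2 fold change| of 3 over residual noise of SD 0.75 (the
    planted effect must clear the |logFC| > 1.5 screening cutoff with
    margin at this sample size), 20 planted triads, about 2 decoy
    interaction pairs per feature, 5 pseudo-databases each reporting a true
    miRNA-mRNA pair with probability 0.9, a planted PPI clique of 6 genes,
    and a 52-patient qPCR cohort.
    """

    n_pairs_per_dataset: int = 10
    n_circ: int = 60
    n_mirna: int = 80
    n_mrna: int = 400
    frac_de: float = 0.3
    effect_lfc: float = 3.0
    noise_sd: float = 0.75
    n_true_triads: int = 20
    decoy_pair_rate: float = 2.0
    n_databases: int = 5
    db_detect_prob: float = 0.9
    ppi_clique_size: int = 6
    ppi_background_edge_prob: float = 0.01
    n_qpcr_patients: int = 52
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_pairs_per_dataset", "n_circ", "n_mirna", "n_mrna",
            "n_databases", "ppi_clique_size", "n_qpcr_patients",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_true_triads < 0:
            raise ValueError("n_true_triads must be >= 0")
        if not (0 < self.frac_de < 1):
            raise ValueError("frac_de must lie in (0, 1)")
        if not (0 <= self.db_detect_prob <= 1):
            raise ValueError("db_detect_prob must lie in [0, 1]")
        if not (0 <= self.ppi_background_edge_prob <= 1):
            raise ValueError("ppi_background_edge_prob must lie in [0, 1]")
        if self.effect_lfc <= 0:
            raise ValueError("effect_lfc must be > 0")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.decoy_pair_rate < 0:
            raise ValueError("decoy_pair_rate must be >= 0")


@dataclass
class SyntheticTruth:
    """The recovery oracle: what was planted."""

    de_features: dict[str, str]  # feature id -> up/down (tumor vs normal)
    true_triads: list[Triad]
    hub_genes: set[str]


@dataclass
class SyntheticStudy:
    """Everything one synthetic run produces."""

    config: SimConfig
    circ_study_a: ExpressionStudy
    circ_study_b: ExpressionStudy
    mirna_study: ExpressionStudy
    mrna_study: ExpressionStudy
    circ_mirna_pairs: list[InteractionPair]
    mirna_mrna_pairs: list[InteractionPair]
    ppi_edges: pd.DataFrame
    annotations: AnnotationCollection
    ct_table: pd.DataFrame
    truth: SyntheticTruth

    def write_all(self, outdir) -> None:
        """Write every table in the TSV formats the pipeline reads."""
        from pathlib import Path
        from .interactions import write_pairs
        from .enrichment import write_annotations

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, study in (
            ("circ_a", self.circ_study_a),
            ("circ_b", self.circ_study_b),
            ("mirna", self.mirna_study),
            ("mrna", self.mrna_study),
        ):
            study.matrix.rename_axis("feature_id").to_csv(outdir / f"{name}_expr.tsv", sep="\t")
            study.design.rename_axis("sample_id").to_csv(outdir / f"{name}_design.tsv", sep="\t")
        write_pairs(self.circ_mirna_pairs, outdir / "circ_mirna_pairs.tsv")
        write_pairs(self.mirna_mrna_pairs, outdir / "mirna_mrna_pairs.tsv")
        self.ppi_edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
        write_annotations(self.annotations, outdir / "annotations.tsv")
        self.ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
        rows = [("de_feature", fid, direction, "", "") for fid, direction in sorted(self.truth.de_features.items())]
        rows += [("triad", t.circ_id, t.mirna_id, t.mrna_id, t.paradigm) for t in self.truth.true_triads]
        rows += [("hub_gene", g, "", "", "") for g in sorted(self.truth.hub_genes)]
        pd.DataFrame(rows, columns=["kind", "a", "b", "c", "d"]).to_csv(
            outdir / "truth.tsv", sep="\t", index=False
        )


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(1, n + 1)]


def _plant_de(ids: list[str], frac_de: float) -> dict[str, str]:
    """First round(frac_de*n) features are DE: first half up, rest down."""
    n_de = int(round(frac_de * len(ids)))
    n_up = (n_de + 1) // 2
    out = {}
    for i, fid in enumerate(ids[:n_de]):
        out[fid] = "up" if i < n_up else "down"
    return out


def _directional(de: dict[str, str], direction: str) -> list[str]:
    return [fid for fid, d in de.items() if d == direction]


def _expression_study(
    rng: np.random.Generator,
    feature_ids: list[str],
    baseline: np.ndarray,
    de: dict[str, str],
    n_pairs: int,
    effect_lfc: float,
    noise_sd: float,
) -> ExpressionStudy:
    shift = np.array(
        [{"up": effect_lfc, "down": -effect_lfc}.get(de.get(fid), 0.0) for fid in feature_ids]
    )
    pair_effect = rng.normal(0.0, 0.5 * noise_sd, size=n_pairs)
    n_feat = len(feature_ids)
    tumor = (
        baseline[:, None]
        + shift[:, None]
        + pair_effect[None, :]
        + rng.normal(0.0, noise_sd, size=(n_feat, n_pairs))
    )
    normal = (
        baseline[:, None]
        + pair_effect[None, :]
        + rng.normal(0.0, noise_sd, size=(n_feat, n_pairs))
    )
    tumor_ids = [f"p{i:02d}_t" for i in range(1, n_pairs + 1)]
    normal_ids = [f"p{i:02d}_n" for i in range(1, n_pairs + 1)]
    matrix = pd.DataFrame(
        np.hstack([tumor, normal]), index=pd.Index(feature_ids, name="feature_id"),
        columns=tumor_ids + normal_ids,
    )
    design = pd.DataFrame(
        {
            "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": [f"p{i:02d}" for i in range(1, n_pairs + 1)] * 2,
        },
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    return ExpressionStudy(matrix, design)


def _plant_triads(cfg: SimConfig, circ_de, mirna_de, mrna_de) -> list[Triad]:
    """Plant paradigm-consistent triads reusing a few circRNAs and miRNAs.

    Mirrors the hub-like topology of real ceRNA subnetworks: few sponges,
    a handful of miRNAs, many target genes (each planted gene appears in
    exactly one triad).
    """
    n_ud = (cfg.n_true_triads + 1) // 2
    n_du = cfg.n_true_triads - n_ud
    triads: list[Triad] = []
    for n_needed, paradigm, c_dir, m_dir, g_dir in (
        (n_ud, UP_DOWN_UP, "up", "down", "up"),
        (n_du, DOWN_UP_DOWN, "down", "up", "down"),
    ):
        if n_needed == 0:
            continue
        circs = _directional(circ_de, c_dir)[:2]
        mirnas = _directional(mirna_de, m_dir)[:4]
        genes = _directional(mrna_de, g_dir)
        if not circs or not mirnas or len(genes) < n_needed:
            raise ValueError(
                f"cannot plant {n_needed} {paradigm} triads: insufficient DE features"
            )
        for i in range(n_needed):
            triads.append(
                Triad(circs[i % len(circs)], mirnas[i % len(mirnas)], genes[i], paradigm)
            )
    return sorted(triads)


def _interaction_catalogs(rng, cfg: SimConfig, triads, circ_ids, mirna_ids, mrna_ids):
    db_names = [f"db{i}" for i in range(1, cfg.n_databases + 1)]
    cm_rows: set[tuple[str, str, str]] = set()
    mg_rows: set[tuple[str, str, str]] = set()
    for t in triads:
        cm_rows.add((t.circ_id, t.mirna_id, CIRC_DB))
    # deterministic iteration: unique (miRNA, gene) pairs in sorted order
    for m, g in sorted({(t.mirna_id, t.mrna_id) for t in triads}):
        reported = rng.random(cfg.n_databases) < cfg.db_detect_prob
        for db, hit in zip(db_names, reported):
            if hit:
                mg_rows.add((m, g, db))
    n_cm_decoys = int(round(cfg.decoy_pair_rate * cfg.n_circ))
    for _ in range(n_cm_decoys):
        c = circ_ids[rng.integers(len(circ_ids))]
        m = mirna_ids[rng.integers(len(mirna_ids))]
        cm_rows.add((c, m, CIRC_DB))
    n_mg_decoys = int(round(cfg.decoy_pair_rate * cfg.n_mirna))
    for _ in range(n_mg_decoys):
        m = mirna_ids[rng.integers(len(mirna_ids))]
        g = mrna_ids[rng.integers(len(mrna_ids))]
        db = db_names[rng.integers(len(db_names))]
        mg_rows.add((m, g, db))
    circ_mirna = merge_pairs(sorted(cm_rows), "circRNA", "miRNA")
    mirna_mrna = merge_pairs(sorted(mg_rows), "miRNA", "mRNA")
    return circ_mirna, mirna_mrna


def _ppi_table(rng, cfg: SimConfig, clique: list[str], mrna_ids: list[str]) -> pd.DataFrame:
    rows = []
    clique_set = set(clique)
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            rows.append((a, b, 0.9))
    n = len(mrna_ids)
    hit = rng.random((n, n)) < cfg.ppi_background_edge_prob
    conf = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if hit[i, j]:
                a, b = mrna_ids[i], mrna_ids[j]
                if a in clique_set and b in clique_set:
                    continue
                rows.append((a, b, round(float(conf[i, j]), 6)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])


def _annotations(rng, cfg: SimConfig, planted_genes: list[str], mrna_ids: list[str]) -> AnnotationCollection:
    """One planted term per category (holding the planted genes) plus
    random background terms of comparable size."""
    collection = AnnotationCollection()
    categories = ("BP", "CC", "MF", "pathway")
    term_size = max(len(planted_genes) + 5, 20)
    for ci, category in enumerate(categories):
        fillers = [
            mrna_ids[int(i)]
            for i in rng.choice(len(mrna_ids), size=term_size - len(planted_genes), replace=False)
        ]
        collection.add(
            f"T{ci:02d}_planted", f"planted {category} term", category,
            set(planted_genes) | set(fillers),
        )
        for b in range(4):
            genes = [
                mrna_ids[int(i)]
                for i in rng.choice(len(mrna_ids), size=term_size, replace=False)
            ]
            collection.add(f"T{ci:02d}_bg{b}", f"background {category} term {b}", category, genes)
    return collection


def _ct_table(rng, cfg: SimConfig, validated_circs: list[tuple[str, str]]) -> pd.DataFrame:
    """Encode planted circRNA fold changes through the ddCt model.

    For an up-regulated circRNA the planted ddCt is -effect_lfc (relative
    expression 2^effect_lfc); additive Normal(0, ct_noise_sd) noise goes on
    each target Ct reading.  Reference gene Ct is held at 15 cycles.
    """
    rows = []
    ref_ct = 15.0
    base_dct = 10.0  # target amplifies 10 cycles after the reference in normal tissue
    for circ_id, direction in validated_circs:
        ddct = -cfg.effect_lfc if direction == "up" else cfg.effect_lfc
        for p in range(1, cfg.n_qpcr_patients + 1):
            pid = f"p{p:02d}"
            ct_normal = ref_ct + base_dct + rng.normal(0.0, cfg.ct_noise_sd)
            ct_tumor = ref_ct + base_dct + ddct + rng.normal(0.0, cfg.ct_noise_sd)
            rows.append((pid, "tumor", circ_id, round(ct_tumor, 4), ref_ct))
            rows.append((pid, "normal", circ_id, round(ct_normal, 4), ref_ct))
    return pd.DataFrame(
        rows, columns=["patient_id", "tissue", "target_gene", "ct_target", "ct_reference"]
    )


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate one complete synthetic study with its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    circ_ids = _ids("circ", cfg.n_circ)
    mirna_ids = _ids("mir", cfg.n_mirna)
    mrna_ids = _ids("gene", cfg.n_mrna)

    circ_de = _plant_de(circ_ids, cfg.frac_de)
    mirna_de = _plant_de(mirna_ids, cfg.frac_de)
    mrna_de = _plant_de(mrna_ids, cfg.frac_de)

    triads = _plant_triads(cfg, circ_de, mirna_de, mrna_de) if cfg.n_true_triads else []

    up_triad_genes = [t.mrna_id for t in triads if t.paradigm == UP_DOWN_UP]
    if cfg.n_true_triads:
        if len(up_triad_genes) < cfg.ppi_clique_size:
            raise ValueError(
                "ppi_clique_size exceeds the planted up-paradigm triad genes; "
                "the hub clique must sit inside the recovered network"
            )
        clique = sorted(up_triad_genes)[: cfg.ppi_clique_size]
    else:
        clique = sorted(_directional(mrna_de, "up"))[: cfg.ppi_clique_size]

    baseline_circ = rng.normal(8.0, 2.0, size=cfg.n_circ)
    baseline_mirna = rng.normal(8.0, 2.0, size=cfg.n_mirna)
    baseline_mrna = rng.normal(8.0, 2.0, size=cfg.n_mrna)

    circ_a = _expression_study(
        rng, circ_ids, baseline_circ, circ_de, cfg.n_pairs_per_dataset, cfg.effect_lfc, cfg.noise_sd
    )
    circ_b = _expression_study(
        rng, circ_ids, baseline_circ, circ_de, cfg.n_pairs_per_dataset, cfg.effect_lfc, cfg.noise_sd
    )
    mirna_study = _expression_study(
        rng, mirna_ids, baseline_mirna, mirna_de, cfg.n_pairs_per_dataset, cfg.effect_lfc, cfg.noise_sd
    )
    mrna_study = _expression_study(
        rng, mrna_ids, baseline_mrna, mrna_de, cfg.n_pairs_per_dataset, cfg.effect_lfc, cfg.noise_sd
    )

    circ_mirna, mirna_mrna = _interaction_catalogs(rng, cfg, triads, circ_ids, mirna_ids, mrna_ids)
    ppi = _ppi_table(rng, cfg, clique, mrna_ids)
    planted_genes = sorted({t.mrna_id for t in triads}) or clique
    annotations = _annotations(rng, cfg, planted_genes, mrna_ids)

    validated = sorted({(t.circ_id, "up") for t in triads if t.paradigm == UP_DOWN_UP})
    if not validated:
        validated = [(cid, circ_de[cid]) for cid in sorted(circ_de)[:2]] if circ_de else []
    ct = _ct_table(rng, cfg, validated)

    de_features = {**circ_de, **mirna_de, **mrna_de}
    truth = SyntheticTruth(de_features=de_features, true_triads=triads, hub_genes=set(clique))
    return SyntheticStudy(
        config=cfg,
        circ_study_a=circ_a,
        circ_study_b=circ_b,
        mirna_study=mirna_study,
        mrna_study=mrna_study,
        circ_mirna_pairs=circ_mirna,
        mirna_mrna_pairs=mirna_mrna,
        ppi_edges=ppi,
        annotations=annotations,
        ct_table=ct,
        truth=truth,
    )
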