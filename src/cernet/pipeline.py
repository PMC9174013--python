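"""End-to-end orchestration of the ceRNA inference stages.

``run_all`` executes simulate (optional) -> differential expression (two
circRNA datasets, miRNAs, mRNAs) -> sign-consistent circRNA intersection
-> database-consensus filtering -> triad assembly -> enrichment -> PPI hub
extraction -> hub subnetwork -> qPCR quantification, writing every
intermediate table, GraphML exports, a JSON run summary and a plain-text
log into the run directory.  Identical config and seed give an identical
summary.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import assemble, export_network, summarize
from .diffexpr import (
    ExpressionStudy,
    de_table,
    intersect_de,
    read_design,
    read_expression,
    write_de_table,
)
from .enrichment import enrich, read_annotations
from .interactions import consensus_filter, load_pairs
from .ppi import build_graph, hub_genes, hub_subnetwork, read_ppi_edges, write_hub_table
from .qpcr import delta_delta_ct, read_ct_table, write_result
from .synthetic import SimConfig, generate_study

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds, input locations and the seed for one pipeline run.

    Either ``simulate`` is set (a synthetic study is generated and written
    under the run directory) or ``inputs`` maps the expected input names to
    existing files: circ_a_expr, circ_a_design, circ_b_expr, circ_b_design,
    mirna_expr, mirna_design, mrna_expr, mrna_design, circ_mirna_pairs,
    mirna_mrna_pairs, ppi_edges, annotations, ct_table.
    """

    lfc_circ: float = 1.5
    lfc_relaxed: float = 0.0  # second circRNA dataset: |logFC| > 0 rule
    lfc_mirna: float = 1.5
    lfc_mrna: float = 1.5
    alpha: float = 0.05
    min_databases: int = 1
    min_confidence: float = 0.4
    min_degree: int = 2
    enrich_alpha: float = 0.05
    top_k: int = 15
    paired_circ: bool = True
    paired_mirna: bool = False
    paired_mrna: bool = False
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.enrich_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        for name in ("lfc_circ", "lfc_relaxed", "lfc_mirna", "lfc_mrna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError("min_confidence must lie in [0, 1]")
        if self.min_databases < 1 or self.min_degree < 0 or self.top_k < 1:
            raise ValueError("invalid count threshold")
        if self.simulate is None and self.inputs is None:
            raise ValueError("either simulate or inputs must be provided")


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; a ``simulate:`` mapping becomes a SimConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw, simulate=SimConfig(**sim) if sim is not None else None)
    return cfg


def _load_study(inputs: dict, prefix: str) -> ExpressionStudy:
    matrix = read_expression(inputs[f"{prefix}_expr"])
    design = read_design(inputs[f"{prefix}_design"])
    return ExpressionStudy(matrix, design)


def _directions(tab: pd.DataFrame) -> dict[str, str]:
    keep = tab[tab["direction"].isin(["up", "down"])]
    return dict(zip(keep.index.astype(str), keep["direction"]))


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage; return the JSON-serializable run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("cernet.pipeline")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    try:
        params = dataclasses.asdict(config)
        params.pop("inputs", None)
        log.info("parameters: %s", json.dumps(params, default=str, sort_keys=True))

        # --- stage: simulate (optional)
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            study = generate_study(sim_cfg)
            input_dir = outdir / "inputs"
            study.write_all(input_dir)
            inputs = {
                name: input_dir / f"{name}.tsv"
                for name in (
                    "circ_a_expr", "circ_a_design", "circ_b_expr", "circ_b_design",
                    "mirna_expr", "mirna_design", "mrna_expr", "mrna_design",
                    "circ_mirna_pairs", "mirna_mrna_pairs", "ppi_edges",
                    "annotations", "ct_table",
                )
            }
            summary["stages"]["simulate"] = {
                "n_planted_triads": len(study.truth.true_triads),
                "n_planted_hubs": len(study.truth.hub_genes),
                "n_planted_de": len(study.truth.de_features),
            }
            log.info("simulate: %s", summary["stages"]["simulate"])
        else:
            inputs = {k: Path(v) for k, v in config.inputs.items()}

        # --- stage: differential expression (4 tables)
        de_specs = [
            ("circ_a", config.lfc_circ, config.paired_circ),
            ("circ_b", config.lfc_relaxed, config.paired_circ),
            ("mirna", config.lfc_mirna, config.paired_mirna),
            ("mrna", config.lfc_mrna, config.paired_mrna),
        ]
        tables = {}
        for name, cutoff, paired in de_specs:
            study_x = _load_study(inputs, name)
            tab = de_table(study_x, paired=paired, lfc_cutoff=cutoff, alpha=config.alpha)
            write_de_table(tab, outdir / f"de_{name}.tsv")
            tables[name] = tab
            counts = tab["direction"].value_counts()
            summary["stages"][f"de_{name}"] = {
                "n_features": int(len(tab)),
                "n_up": int(counts.get("up", 0)),
                "n_down": int(counts.get("down", 0)),
            }
            log.info("de %s: %s", name, summary["stages"][f"de_{name}"])

        # --- stage: sign-consistent intersection of the two circRNA datasets
        overlap = intersect_de(tables["circ_a"], tables["circ_b"])
        circ_directions = {fid: "up" for fid in overlap["up"]}
        circ_directions.update({fid: "down" for fid in overlap["down"]})
        pd.DataFrame(
            sorted((fid, d) for fid, d in circ_directions.items()),
            columns=["feature_id", "direction"],
        ).to_csv(outdir / "circ_intersection.tsv", sep="\t", index=False)
        summary["stages"]["intersect"] = {
            "n_up": len(overlap["up"]),
            "n_down": len(overlap["down"]),
        }
        log.info("intersect: %s", summary["stages"]["intersect"])

        # --- stage: interaction catalogs and consensus
        circ_mirna = load_pairs(inputs["circ_mirna_pairs"], "circRNA", "miRNA")
        mirna_mrna = load_pairs(inputs["mirna_mrna_pairs"], "miRNA", "mRNA")
        mirna_mrna = consensus_filter(mirna_mrna, config.min_databases)
        summary["stages"]["consensus"] = {
            "n_circ_mirna_pairs": len(circ_mirna),
            "n_mirna_mrna_pairs": len(mirna_mrna),
        }
        log.info("consensus: %s", summary["stages"]["consensus"])

        # --- stage: triad assembly
        network = assemble(
            circ_mirna,
            mirna_mrna,
            circ_directions,
            _directions(tables["mirna"]),
            _directions(tables["mrna"]),
        )
        export_network(network, outdir / "cerna_network.graphml", "graphml")
        export_network(network, outdir / "cerna_triads.tsv", "tsv")
        summary["stages"]["assemble"] = summarize(network)
        log.info("assemble: %s", summary["stages"]["assemble"])

        # --- stage: enrichment of the network mRNAs
        collection = read_annotations(inputs["annotations"])
        universe = set(tables["mrna"].index.astype(str))
        enriched = enrich(
            network.mrna_ids,
            collection,
            universe=universe,
            alpha=config.enrich_alpha,
            top_k=config.top_k,
        )
        enriched.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrich"] = {"n_significant_terms": int(len(enriched))}
        log.info("enrich: %s", summary["stages"]["enrich"])

        # --- stage: PPI graph and hub genes
        ppi_edges = read_ppi_edges(inputs["ppi_edges"])
        graph = build_graph(ppi_edges, network.mrna_ids, config.min_confidence)
        hubs = hub_genes(graph, config.min_degree)
        write_hub_table(hubs, outdir / "hub_genes.tsv")
        summary["stages"]["hubs"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_hubs": len(hubs),
        }
        log.info("hubs: %s", summary["stages"]["hubs"])

        # --- stage: hub subnetwork
        sub = hub_subnetwork(network, {h.gene_id for h in hubs})
        export_network(sub, outdir / "hub_subnetwork.graphml", "graphml")
        export_network(sub, outdir / "hub_subnetwork.tsv", "tsv")
        summary["stages"]["subnetwork"] = summarize(sub)
        log.info("subnetwork: %s", summary["stages"]["subnetwork"])

        # --- stage: qPCR (optional: runs when a Ct table is present)
        ct_path = inputs.get("ct_table")
        if ct_path is not None and Path(ct_path).exists():
            ct = read_ct_table(ct_path)
            qpcr_summary = {}
            for target in sorted(ct["target_gene"].unique()):
                result = delta_delta_ct(ct, target_gene=target)
                write_result(result, outdir / f"qpcr_{target}.tsv")
                qpcr_summary[target] = {
                    "mean_fold_change": round(result.mean_fold_change, 6),
                    "sd_fold_change": round(result.sd_fold_change, 6),
                    "t": round(result.t_stat, 6),
                    "df": result.df,
                    "p_value": result.p_value,
                }
            summary["stages"]["qpcr"] = qpcr_summary
            log.info("qpcr: %s", qpcr_summary)

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("run complete")
        return summary
    except Exception as exc:  # annotate the failing stage, then re-raise
        done = list(summary["stages"])
        log.error("failed after stages %s: %s", done, exc)
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
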