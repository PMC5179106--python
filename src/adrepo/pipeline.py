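"""End-to-end orchestration: assemble -> network -> score -> rank -> drugs -> enrich.

A *bundle directory* holds the input tables under canonical names (see
``adrepo.synthetic_data.BUNDLE_FILENAMES``); required are the four evidence tables
and the link table, while the drug catalog, annotations, gene map, PPI edge list and
GMT pathway file are optional (stages needing them are skipped with a note in the run
log).  All outputs are plain text and byte-deterministic for a given bundle, so two
runs on the same inputs produce identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import drug_repositioning, enrichment, networks, scoring, target_assembly
from .evidence_io import (ScoringConfig, read_annotations, read_drug_catalog,
                          read_evidence_bundle, read_gene_map, read_gmt, write_network)
from .synthetic_data import BUNDLE_FILENAMES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Everything one run needs: input locations, scoring knobs, thresholds."""

    model_config = ConfigDict(frozen=True)

    bundle_dir: Path
    out_dir: Path
    scoring: ScoringConfig = Field(default_factory=ScoringConfig)
    resolution: str = "max"
    min_links: int = Field(default=2, ge=1)
    hub_min_degree: int = Field(default=10, ge=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    internal_control: str | None = None
    known_targets: tuple[str, ...] = ("ACHE", "APP")

    def config_hash(self) -> str:
        # hash the analysis settings only, not the incidental input/output locations
        payload = self.model_dump(mode="json", exclude={"bundle_dir", "out_dir"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles on everything the run wrote."""

    targets: pd.DataFrame
    multiplatform: pd.DataFrame
    ranked: pd.DataFrame
    candidates: pd.DataFrame
    summary: pd.DataFrame
    enrichment: pd.DataFrame | None
    hubs: list[tuple[str, int]]
    log_lines: list[str] = field(default_factory=list)


def _bundle_path(bundle_dir: Path, key: str) -> Path | None:
    path = bundle_dir / BUNDLE_FILENAMES[key]
    return path if path.exists() else None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a bundle directory, writing all outputs under ``out_dir``."""
    bundle_dir, out_dir = Path(config.bundle_dir), Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash\t{config.config_hash()}"]

    # --- read ---------------------------------------------------------------
    paths = {}
    for key in ("genetics", "epigenetics", "proteomics", "metabolomics", "links"):
        path = _bundle_path(bundle_dir, key)
        if path is None:
            raise FileNotFoundError(f"bundle is missing required table: {BUNDLE_FILENAMES[key]}")
        paths[key] = path
    evidence = read_evidence_bundle(paths)
    for key, df in evidence.items():
        log.append(f"read\t{key}\t{len(df)}\trejected={len(df.attrs.get('rejected', []))}")

    gene_map: dict[str, str] = {}
    if (p := _bundle_path(bundle_dir, "gene_map")) is not None:
        gene_map = read_gene_map(p)

    # --- assemble -----------------------------------------------------------
    met_targets = target_assembly.collect_metabolite_proteins(
        evidence["links"], evidence["metabolomics"], min_links=config.min_links)
    targets = target_assembly.assemble_targets(
        genetic=evidence["genetics"], epigenetic=evidence["epigenetics"],
        proteomic=evidence["proteomics"], metabolite_targets=met_targets,
        gene_map=gene_map)
    multi = target_assembly.multiplatform_targets(targets)
    target_assembly.write_targets(targets, out_dir / "targets.tsv")
    target_assembly.write_targets(multi, out_dir / "multiplatform_targets.tsv")
    log.append(f"assembled\ttargets\t{len(targets)}")
    log.append(f"assembled\tmultiplatform\t{len(multi)}")

    # --- networks -----------------------------------------------------------
    bipartite = networks.build_bipartite(evidence["links"], evidence["metabolomics"],
                                         min_changed=config.min_links)
    write_network(bipartite, out_dir / "metabolite_protein.sif", "SIF")
    write_network(bipartite, out_dir / "metabolite_protein.graphml", "GraphML")
    log.append(f"network\tbipartite_nodes\t{bipartite.number_of_nodes()}")
    log.append(f"network\tbipartite_edges\t{bipartite.number_of_edges()}")

    hubs: list[tuple[str, int]] = []
    ppi = None
    if (p := _bundle_path(bundle_dir, "ppi_edges")) is not None:
        ppi = networks.read_ppi_edges(p)
        hubs = networks.find_hubs(ppi, min_degree=config.hub_min_degree)
        pd.DataFrame(hubs, columns=["node", "degree"]).to_csv(
            out_dir / "ppi_hubs.tsv", sep="\t", index=False)
        if hubs:
            write_network(networks.hub_neighborhood(ppi, hubs[0][0]),
                          out_dir / "hub_neighborhood.sif", "SIF")
        log.append(f"network\tppi_hubs\t{len(hubs)}")
    else:
        log.append("network\tppi_edges\tabsent")

    # --- score and rank -----------------------------------------------------
    annotations = pd.DataFrame()
    if (p := _bundle_path(bundle_dir, "annotations")) is not None:
        annotations = read_annotations(p)
    ranked_list = scoring.score_targets(
        targets, genetic=evidence["genetics"], proteomic=evidence["proteomics"],
        metabolomic=evidence["metabolomics"], annotations=annotations,
        gene_map=gene_map, config=config.scoring, resolution=config.resolution,
        internal_control=config.internal_control)
    symbols = dict(zip(targets["uniprot_id"], targets["gene_symbol"]))
    scoring.write_ranked(ranked_list, out_dir / "ranked_targets.tsv", gene_symbols=symbols)
    ranked = scoring.read_ranked(out_dir / "ranked_targets.tsv")
    log.append(f"scored\ttargets\t{len(ranked_list)}")

    # --- drugs --------------------------------------------------------------
    candidates = pd.DataFrame(columns=drug_repositioning.CANDIDATE_COLUMNS)
    if (p := _bundle_path(bundle_dir, "drugs")) is not None and not annotations.empty:
        catalog = read_drug_catalog(p)
        ranked_frame = scoring.ranked_to_frame(ranked_list, gene_symbols=symbols)
        candidates = drug_repositioning.build_candidates(
            ranked_frame, catalog, annotations, known_targets=config.known_targets)
        log.append(f"drugs\tcatalog_rows\t{len(catalog)}")
    else:
        log.append("drugs\tcatalog\tabsent_or_unannotated")
    summary = drug_repositioning.summarize(candidates)
    candidates.to_csv(out_dir / "drug_candidates.tsv", sep="\t", index=False)
    summary.to_csv(out_dir / "target_summary.tsv", sep="\t", index=False)
    log.append(f"drugs\tcandidate_pairs\t{len(candidates)}")
    log.append(f"drugs\ttargets_with_drugs\t{summary['uniprot_id'].nunique() if not summary.empty else 0}")

    # --- enrichment ---------------------------------------------------------
    enrich_table: pd.DataFrame | None = None
    if (p := _bundle_path(bundle_dir, "gmt")) is not None:
        gene_sets = read_gmt(p)
        if hubs and ppi is not None:
            neighborhood = networks.hub_neighborhood(ppi, hubs[0][0])
            query = {symbols.get(n, n) for n in neighborhood.nodes}
        else:
            query = set(targets["gene_symbol"]) - {""}
        query &= gene_sets.universe
        if query:
            enrich_table = enrichment.enrich(query, gene_sets, alpha=config.alpha)
            enrich_table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            log.append(f"enrichment\tpathways_tested\t{len(enrich_table)}")
            log.append(f"enrichment\tsignificant\t{int(enrich_table['significant'].sum())}")
        else:
            log.append("enrichment\tquery\tempty_after_universe")
    else:
        log.append("enrichment\tgmt\tabsent")

    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    for line in log:
        logger.info(line.replace("\t", " "))
    return PipelineResult(targets=targets, multiplatform=multi, ranked=ranked,
                          candidates=candidates, summary=summary,
                          enrichment=enrich_table, hubs=hubs, log_lines=log)
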