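"""Seeded generator for a complete synthetic evidence bundle with planted ground truth.

The generator emulates the structure of the hand-curated inputs the pipeline expects —
GWAS associations, epigenetic events, CSF proteomic changes, altered metabolites, an
HMDB-style link table, a drug catalog, pathogenesis annotations, a gene map, a
String-style PPI edge list and a GMT pathway file — at desk scale, so the whole
pipeline is testable without downloads.

Background evidence is drawn to sit below the internal-control references: odds ratios
are lognormal around typical GWAS effects (median 1.15) resampled to stay at or below
the 3.7 reference, fold magnitudes are ``1 + Exponential(mean 0.6)`` resampled to stay
at or below the 2.37 reference, and citation/publication counts follow a discrete
power law truncated at the 4092/11294 references.  Background target scores therefore
concentrate around the mid-0.2 range typical of novel targets, and no background
target can reach the control score of 1.

``planted_targets`` accessions receive every score component multiplied by
``plant_boost`` (default 3).  Planted targets are assigned the proteomics or
metabolomics platform (alternating): a multiplicative boost on the GWAS background,
which sits roughly three-fold below its reference, would not produce a top-ranked
target.  Planted metabolomics targets get dedicated altered metabolites (not shared
with the background) carrying the boosted fold changes, so the planted signal stays
attributable.  With the default boost the weakest planted effect term is
``0.33 * 3 / 2.37 = 0.418``, above everything the truncated background can reach, so
planted targets sort to the top of the ranking by construction.

Same seed, same config => byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import scoring
from .drug_repositioning import ELIGIBLE_STAGES, assess_compatibility
from .evidence_io import load_moa_classes

__all__ = ["GeneratorConfig", "GroundTruth", "Bundle", "BUNDLE_FILENAMES",
           "generate_bundle", "generate_worked_example"]

#: canonical file names of a bundle directory
BUNDLE_FILENAMES = {
    "genetics": "gwas.tsv",
    "epigenetics": "epigenetics.tsv",
    "proteomics": "proteomics.tsv",
    "metabolomics": "metabolomics.tsv",
    "links": "metabolite_protein_links.tsv",
    "drugs": "drug_catalog.tsv",
    "annotations": "pathogenesis.tsv",
    "gene_map": "gene_map.tsv",
    "ppi_edges": "ppi_edges.tsv",
    "gmt": "pathways.gmt",
    "ground_truth": "ground_truth.json",
}

_SCOREABLE = ("genetics", "proteomics", "metabolomics")
_PLANT_PLATFORMS = ("proteomics", "metabolomics")
_STAGE_TEXT = {"approved": "Approved", "experimental": "Experimental"}
_PHASES = ("Phase I", "Phase II", "Phase III")
_INDICATIONS = ("leukemia", "hypertension", "diabetes", "solid tumor",
                "depression", "epilepsy", "asthma", "arthritis")


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic bundle; defaults are the package's study conditions."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_targets: int = Field(default=500, ge=1)
    n_metabolites: int = Field(default=86, ge=2)
    n_drugs: int = Field(default=120, ge=0)
    planted_targets: int = Field(default=5, ge=0)
    plant_boost: float = Field(default=3.0, gt=0)
    link_degree_mean: float = Field(default=2.0, gt=0)
    n_multiplatform: int = Field(default=8, ge=0)
    annotation_fraction: float = Field(default=0.85, ge=0, le=1)
    platform_fractions: dict[str, float] = Field(default_factory=lambda: {
        "genetics": 0.42, "proteomics": 0.19, "metabolomics": 0.36, "epigenetics": 0.03})
    stage_mix: dict[str, float] = Field(default_factory=lambda: {
        "approved": 0.4, "clinical_trial": 0.3, "experimental": 0.3})
    mode_mix: dict[str, float] = Field(default_factory=lambda: {
        "inhibitor": 0.25, "antagonist": 0.10, "antibody": 0.10, "blocker": 0.05,
        "agonist": 0.15, "activator": 0.10, "inducer": 0.05,
        "substrate": 0.10, "modulator": 0.05, "unknown": 0.05})

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if self.planted_targets > self.n_targets:
            raise ValueError(f"planted_targets={self.planted_targets} > n_targets={self.n_targets}")
        if self.planted_targets + self.n_multiplatform > self.n_targets:
            raise ValueError("planted_targets + n_multiplatform exceeds n_targets")
        for name, mix in (("platform_fractions", self.platform_fractions),
                          ("stage_mix", self.stage_mix), ("mode_mix", self.mode_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total!r}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
        vocab = {t for ts in load_moa_classes().values() for t in ts}
        bad = set(self.mode_mix) - vocab
        if bad:
            raise ValueError(f"mode_mix tokens outside the vocabulary: {sorted(bad)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}))


@dataclass
class GroundTruth:
    """What was planted: accessions, true score components and guaranteed drug pairs."""

    planted: list[str]
    components: dict[str, dict[str, Any]]
    planted_pairs: list[dict[str, str]]
    hub: str | None = None
    enriched_pathway: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "planted": self.planted,
            "components": self.components,
            "planted_pairs": self.planted_pairs,
            "hub": self.hub,
            "enriched_pathway": self.enriched_pathway,
        }, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


@dataclass
class Bundle:
    """All generated input tables plus the planted ground truth."""

    tables: dict[str, pd.DataFrame]
    gmt_lines: list[str]
    ground_truth: GroundTruth
    config: GeneratorConfig | None = None

    def write(self, outdir: str | Path) -> Path:
        """Write every table under its canonical bundle file name."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(outdir / BUNDLE_FILENAMES[key], sep="\t", index=False)
        (outdir / BUNDLE_FILENAMES["gmt"]).write_text(
            "\n".join(self.gmt_lines) + ("\n" if self.gmt_lines else ""), encoding="utf-8")
        self.ground_truth.to_json(outdir / BUNDLE_FILENAMES["ground_truth"])
        return outdir


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------


def _draw_or(rng: np.random.Generator, cap: float = 3.7) -> float:
    """Background GWAS odds ratio: lognormal around 1.15, resampled to <= cap."""
    while True:
        value = float(rng.lognormal(mean=np.log(1.15), sigma=0.15))
        if value <= cap:
            return round(value, 4)


def _draw_fold(rng: np.random.Generator, cap: float = 2.37) -> float:
    """Background fold magnitude: 1 + Exponential(mean 0.6), resampled to <= cap."""
    while True:
        value = 1.0 + float(rng.exponential(scale=0.6))
        if value <= cap:
            return round(value, 4)


def _draw_count(rng: np.random.Generator, cap: int) -> int:
    """Background citation/publication count: zipf(2) resampled to <= cap."""
    while True:
        value = int(rng.zipf(a=2.0))
        if value <= cap:
            return value


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    return str(rng.choice(keys, p=[mix[k] for k in keys]))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_bundle(config: GeneratorConfig | None = None) -> Bundle:
    """Generate the full synthetic bundle described by ``config`` (deterministic)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    nt = cfg.n_targets

    accessions = [f"P{i + 1:05d}" for i in range(nt)]
    symbols = [f"GENE{i + 1:04d}" for i in range(nt)]

    # --- platform assignment -------------------------------------------------
    frac_keys = sorted(cfg.platform_fractions)
    primary = [str(p) for p in rng.choice(frac_keys, size=nt,
                                          p=[cfg.platform_fractions[k] for k in frac_keys])]
    planted_idx = sorted(int(i) for i in rng.choice(nt, size=cfg.planted_targets, replace=False))
    platforms: list[set[str]] = [{p} for p in primary]
    for j, i in enumerate(planted_idx):
        platforms[i] = {_PLANT_PLATFORMS[j % len(_PLANT_PLATFORMS)]}
    non_planted = [i for i in range(nt) if i not in set(planted_idx)]
    multi_idx = sorted(int(i) for i in rng.choice(non_planted, size=min(cfg.n_multiplatform, len(non_planted)),
                                                  replace=False)) if non_planted else []
    for i in multi_idx:
        others = sorted(set(frac_keys) - platforms[i])
        platforms[i].add(str(rng.choice(others)))

    planted_acc = [accessions[i] for i in planted_idx]
    planted_set = set(planted_idx)
    components: dict[str, dict[str, Any]] = {
        accessions[i]: {"platforms": sorted(platforms[i]), "planted": i in planted_set}
        for i in range(nt)
    }

    # --- genetics ------------------------------------------------------------
    gwas_rows = []
    snp_counter = 0
    for i in range(nt):
        if "genetics" not in platforms[i]:
            continue
        n_snps = 1 + int(rng.poisson(0.3))
        best = 0.0
        for _ in range(n_snps):
            snp_counter += 1
            or_value = _draw_or(rng)
            best = max(best, or_value)
            gwas_rows.append({
                "gene_symbol": symbols[i],
                "snp_id": f"rs{100000 + snp_counter}",
                "odds_ratio": or_value,
                "p_value": float(f"{10 ** -rng.uniform(5, 12):.3e}"),
                "initial_n": int(rng.integers(5000, 50000)),
                "replication_n": int(rng.integers(2000, 20000)),
                "pubmed_id": f"{20000000 + snp_counter}",
            })
        components[accessions[i]]["odds_ratio"] = best

    # --- proteomics ----------------------------------------------------------
    prot_rows = []
    for i in range(nt):
        if "proteomics" not in platforms[i]:
            continue
        magnitude = _draw_fold(rng)
        if i in planted_set:
            magnitude = round(magnitude * cfg.plant_boost, 4)
        fold = magnitude * (1 if rng.random() < 0.5 else -1)
        prot_rows.append({
            "uniprot_id": accessions[i], "gene_symbol": symbols[i],
            "fold_change": fold, "sample_type": "CSF",
            "pubmed_id": f"{21000000 + i}",
        })
        components[accessions[i]]["fold_change"] = fold

    # --- epigenetics ---------------------------------------------------------
    epi_rows = []
    for i in range(nt):
        if "epigenetics" not in platforms[i]:
            continue
        epi_rows.append({
            "gene_symbol": symbols[i], "uniprot_id": accessions[i],
            "direction": str(rng.choice(["hyper", "hypo", "altered"])),
            "pubmed_id": f"{22000000 + i}",
        })

    # --- metabolomics and the link table -------------------------------------
    changed_ids = [f"HMDB{i + 1:07d}" for i in range(cfg.n_metabolites)]
    unchanged_ids = [f"HMDB{cfg.n_metabolites + i + 1:07d}" for i in range(cfg.n_metabolites)]
    met_rows = [{
        "metabolite_id": mid,
        "name": f"metabolite_{mid[-4:]}",
        "fold_change": _draw_fold(rng) * (1 if rng.random() < 0.5 else -1),
        "sample_type": str(rng.choice(["CSF", "plasma", "serum"])),
    } for mid in changed_ids]

    link_rows: list[dict[str, str]] = []
    extra_met_counter = 0
    for i in range(nt):
        if "metabolomics" not in platforms[i]:
            continue
        if i in planted_set:
            # dedicated altered metabolites carrying the boosted fold changes
            mids = []
            for _ in range(3):
                extra_met_counter += 1
                mid = f"HMDB{2 * cfg.n_metabolites + extra_met_counter:07d}"
                met_rows.append({
                    "metabolite_id": mid,
                    "name": f"metabolite_{mid[-4:]}",
                    "fold_change": round(_draw_fold(rng) * cfg.plant_boost, 4)
                                   * (1 if rng.random() < 0.5 else -1),
                    "sample_type": "CSF",
                })
                mids.append(mid)
        else:
            k = min(2 + int(rng.poisson(1.0)), len(changed_ids))
            mids = [str(m) for m in rng.choice(changed_ids, size=k, replace=False)]
            extra = int(rng.poisson(cfg.link_degree_mean))
            if extra:
                mids += [str(m) for m in rng.choice(unchanged_ids,
                                                    size=min(extra, len(unchanged_ids)),
                                                    replace=False)]
        link_rows += [{"metabolite_id": m, "uniprot_id": accessions[i]} for m in mids]

    # background link noise: extra partners per shared-pool metabolite
    background_acc = [accessions[i] for i in non_planted]
    if background_acc:
        for mid in changed_ids + unchanged_ids:
            for _ in range(int(rng.poisson(cfg.link_degree_mean / 2))):
                link_rows.append({"metabolite_id": mid,
                                  "uniprot_id": str(rng.choice(background_acc))})
    links = pd.DataFrame(link_rows, columns=["metabolite_id", "uniprot_id"])
    links = links.drop_duplicates().sort_values(["metabolite_id", "uniprot_id"]).reset_index(drop=True)

    metabolomics = pd.DataFrame(met_rows, columns=["metabolite_id", "name", "fold_change", "sample_type"])
    fold_by_metabolite = {r["metabolite_id"]: r["fold_change"] for r in met_rows}
    changed_all = set(fold_by_metabolite)
    for protein, group in links.groupby("uniprot_id"):
        partners = set(group["metabolite_id"])
        hit = sorted(partners & changed_all)
        if protein in components:
            components[protein]["N"] = len(partners)
            components[protein]["n"] = len(hit)
            components[protein]["metabolite_folds"] = [fold_by_metabolite[m] for m in hit]

    # realized platforms: metabolomics membership is what the >=2-altered-metabolite
    # inclusion rule will find, which background link noise can extend
    for i in range(nt):
        comp = components[accessions[i]]
        realized = set(comp["platforms"]) - {"metabolomics"}
        if comp.get("n", 0) >= 2:
            realized.add("metabolomics")
        comp["platforms"] = sorted(realized)

    # --- pathogenesis annotations --------------------------------------------
    ann_rows = []
    for i in range(nt):
        annotated = (i in planted_set) or (rng.random() < cfg.annotation_fraction)
        citations = _draw_count(rng, 4092)
        publications = _draw_count(rng, 11294)
        role = str(rng.choice(["GOF", "LOF", "unknown"], p=[0.4, 0.35, 0.25]))
        if i in planted_set:
            j = planted_idx.index(i)
            role = "GOF" if j % 2 == 0 else "LOF"
            citations = int(round(citations * cfg.plant_boost))
            publications = int(round(publications * cfg.plant_boost))
        if not annotated:
            continue
        ann_rows.append({"uniprot_id": accessions[i], "role": role,
                         "citation_count": citations, "publication_count": publications})
        components[accessions[i]]["role"] = role
        components[accessions[i]]["C"] = citations
        components[accessions[i]]["H"] = publications
    annotations = pd.DataFrame(ann_rows, columns=["uniprot_id", "role",
                                                  "citation_count", "publication_count"])

    # --- drug catalog ---------------------------------------------------------
    drug_rows = []
    for j in range(cfg.n_drugs):
        stage = _choice(rng, cfg.stage_mix)
        stage_text = _STAGE_TEXT.get(stage) or str(rng.choice(_PHASES))
        drug_rows.append({
            "drug_name": f"DRUG{j + 1:04d}",
            "target_uniprot": str(rng.choice(accessions)),
            "stage": stage_text,
            "mode_of_action": _choice(rng, cfg.mode_mix),
            "original_indication": str(rng.choice(_INDICATIONS)),
            "source_db": str(rng.choice(["TTD", "DrugBank"])),
        })
    for j, acc in enumerate(planted_acc):
        role = components[acc]["role"]
        mode = ("inhibitor", "antibody")[j % 2] if role == "GOF" else ("activator", "agonist")[j % 2]
        drug_rows.append({
            "drug_name": f"DRUGP{j + 1:02d}",
            "target_uniprot": acc,
            "stage": "Approved" if j % 2 == 0 else "Phase II",
            "mode_of_action": mode,
            "original_indication": str(rng.choice(_INDICATIONS)),
            "source_db": "TTD",
        })
    drugs = pd.DataFrame(drug_rows, columns=["drug_name", "target_uniprot", "stage",
                                             "mode_of_action", "original_indication", "source_db"])

    # --- gene map, PPI edges, pathways ---------------------------------------
    gene_map = pd.DataFrame({"gene_symbol": symbols, "uniprot_id": accessions})

    ppi_rows = []
    hub_acc = None
    if len(background_acc) >= 12:
        hub_acc = str(rng.choice(background_acc))
        pool = sorted(set(background_acc) - {hub_acc})
        neighbors = [str(a) for a in rng.choice(pool, size=10, replace=False)]
        for nb in neighbors:
            ppi_rows.append({"protein_a": hub_acc, "protein_b": nb,
                             "combined_score": int(rng.integers(400, 999))})
        for _ in range(nt // 2):
            a, b = (str(x) for x in rng.choice(accessions, size=2, replace=False))
            ppi_rows.append({"protein_a": a, "protein_b": b,
                             "combined_score": int(rng.integers(150, 999))})
    ppi = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "combined_score"])

    gmt_lines: list[str] = []
    enriched_pathway = None
    if nt >= 30:
        symbol_of = dict(zip(accessions, symbols))
        if hub_acc is not None:
            core = [symbol_of[a] for a in neighbors[:5]]
            filler = [str(s) for s in rng.choice(symbols, size=10, replace=False)]
            enriched_pathway = "hub_core_metabolism"
            gmt_lines.append("\t".join([enriched_pathway, "planted enriched set",
                                        *sorted(set(core + filler))]))
        for p in range(10):
            size = int(rng.integers(10, 40))
            members = sorted(str(s) for s in rng.choice(symbols, size=size, replace=False))
            gmt_lines.append("\t".join([f"pathway_{p + 1:02d}", "random set", *members]))

    # --- true scores ----------------------------------------------------------
    for i in range(nt):
        acc = accessions[i]
        comp = components[acc]
        candidates = []
        citations, publications = comp.get("C", 0), comp.get("H", 0)
        if "odds_ratio" in comp:
            candidates.append(scoring.score_genetic(comp["odds_ratio"], citations, publications).total)
        if "fold_change" in comp:
            candidates.append(scoring.score_proteomic(comp["fold_change"], citations, publications).total)
        if comp.get("n", 0) >= 1 and comp.get("metabolite_folds"):
            candidates.append(scoring.score_metabolomic(
                [abs(f) for f in comp["metabolite_folds"]], comp["N"],
                citations, publications).total)
        comp["true_score"] = max(candidates) if candidates else None

    eligible_stage = {"Approved": "approved", "Phase I": "clinical_trial",
                      "Phase II": "clinical_trial", "Phase III": "clinical_trial"}
    classes = load_moa_classes()
    planted_pairs = []
    for row in drugs.itertuples(index=False):
        if row.target_uniprot in set(planted_acc) and row.stage in eligible_stage:
            planted_pairs.append({
                "uniprot_id": row.target_uniprot,
                "drug_name": row.drug_name,
                "stage": eligible_stage[row.stage],
                "mode_of_action": row.mode_of_action,
                "compatibility": assess_compatibility(
                    components[row.target_uniprot]["role"], row.mode_of_action, classes),
            })

    truth = GroundTruth(planted=planted_acc, components=components,
                        planted_pairs=planted_pairs, hub=hub_acc,
                        enriched_pathway=enriched_pathway)
    tables = {
        "genetics": pd.DataFrame(gwas_rows, columns=["gene_symbol", "snp_id", "odds_ratio",
                                                     "p_value", "initial_n", "replication_n", "pubmed_id"]),
        "epigenetics": pd.DataFrame(epi_rows, columns=["gene_symbol", "uniprot_id", "direction", "pubmed_id"]),
        "proteomics": pd.DataFrame(prot_rows, columns=["uniprot_id", "gene_symbol", "fold_change",
                                                       "sample_type", "pubmed_id"]),
        "metabolomics": metabolomics,
        "links": links,
        "drugs": drugs,
        "annotations": annotations,
        "gene_map": gene_map,
        "ppi_edges": ppi,
    }
    return Bundle(tables=tables, gmt_lines=gmt_lines, ground_truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------


def generate_worked_example() -> Bundle:
    """A fixed, seed-free 19-target bundle with hand-checkable counts.

    Contents (all synthetic, shaped like the real curated tables):

    * 19 candidate targets: the internal control ``P05067`` (proteomics, evidence
      exactly at the reference constants, so its computed score is 1 even before the
      control override), 6 genetics targets ``P10001``-``P10006``, 6 further
      proteomics targets ``P20001``-``P20006`` and 6 metabolomics targets
      ``P30001``-``P30006`` (each linked to 2 altered + 1 unaltered metabolite,
      so N=3, n=2).
    * 16 of the 19 have pathogenesis annotations; ``P10006``, ``P20006`` and
      ``P30006`` do not and are therefore excluded from drug candidates.
    * 24 catalog drugs cycling through stages Approved / Phase II / Experimental and
      through the mode-of-action vocabulary; 16 are approved or clinical-trial, of
      which 3 hit the unannotated targets, so the drug-candidate table has exactly
      13 rows.
    """
    # control: evidence exactly at the references
    prot_rows = [{"uniprot_id": "P05067", "gene_symbol": "APP", "fold_change": 2.37,
                  "sample_type": "CSF", "pubmed_id": "10000001"}]
    ann_rows = [{"uniprot_id": "P05067", "role": "GOF",
                 "citation_count": 4092, "publication_count": 11294}]
    gwas_rows, met_rows, link_rows, map_rows = [], [], [], []
    map_rows.append({"gene_symbol": "APP", "uniprot_id": "P05067"})

    roles = ["GOF", "LOF", "GOF", "LOF", "GOF", "unknown"]
    for i in range(6):
        acc, sym = f"P1000{i + 1}", f"GWG{i + 1:02d}"
        gwas_rows.append({"gene_symbol": sym, "snp_id": f"rs{1000 + i}",
                          "odds_ratio": round(1.2 + 0.4 * i, 2), "p_value": 1e-8,
                          "initial_n": 20000, "replication_n": 10000,
                          "pubmed_id": f"{1100 + i}"})
        map_rows.append({"gene_symbol": sym, "uniprot_id": acc})
        if i < 5:
            ann_rows.append({"uniprot_id": acc, "role": roles[i],
                             "citation_count": 200 * (i + 1), "publication_count": 500 * (i + 1)})

    for i in range(6):
        acc, sym = f"P2000{i + 1}", f"PRG{i + 1:02d}"
        fold = round((1.3 + 0.2 * i) * (1 if i % 2 == 0 else -1), 2)
        prot_rows.append({"uniprot_id": acc, "gene_symbol": sym, "fold_change": fold,
                          "sample_type": "CSF", "pubmed_id": f"{1200 + i}"})
        map_rows.append({"gene_symbol": sym, "uniprot_id": acc})
        if i < 5:
            ann_rows.append({"uniprot_id": acc, "role": roles[i],
                             "citation_count": 100 * (i + 1), "publication_count": 300 * (i + 1)})

    for i in range(6):
        acc, sym = f"P3000{i + 1}", f"MTG{i + 1:02d}"
        changed = [f"HMDB{2 * i + 1:07d}", f"HMDB{2 * i + 2:07d}"]
        unchanged = f"HMDB{100 + i:07d}"
        for j, mid in enumerate(changed):
            met_rows.append({"metabolite_id": mid, "name": f"met_{mid[-3:]}",
                             "fold_change": round((1.5 + 0.1 * i) * (1 if j == 0 else -1), 2),
                             "sample_type": "CSF"})
        link_rows += [{"metabolite_id": m, "uniprot_id": acc} for m in changed + [unchanged]]
        map_rows.append({"gene_symbol": sym, "uniprot_id": acc})
        if i < 5:
            ann_rows.append({"uniprot_id": acc, "role": roles[i],
                             "citation_count": 50 * (i + 1), "publication_count": 150 * (i + 1)})

    # 24 drugs: stages and modes cycle deterministically
    stages = ["Approved", "Phase II", "Experimental"]
    modes = ["inhibitor", "antibody", "agonist", "activator", "substrate", "unknown"]
    targets_cycle = (["P05067", "P10001", "P10002", "P10003", "P10004", "P10005", "P10006"]
                     + [f"P2000{i}" for i in range(1, 7)] + [f"P3000{i}" for i in range(1, 7)])
    drug_rows = []
    for j in range(24):
        drug_rows.append({
            "drug_name": f"WDRUG{j + 1:02d}",
            "target_uniprot": targets_cycle[j % len(targets_cycle)],
            "stage": stages[j % 3],
            "mode_of_action": modes[j % 6],
            "original_indication": _INDICATIONS[j % len(_INDICATIONS)],
            "source_db": "TTD" if j % 2 == 0 else "DrugBank",
        })

    epi_rows: list[dict] = []
    ppi_rows = [{"protein_a": "P30001", "protein_b": f"P3000{i}", "combined_score": 900}
                for i in range(2, 5)]
    gmt_lines = [
        "\t".join(["worked_pathway_a", "synthetic set",
                   "MTG01", "MTG02", "MTG03", "GWG01", "PRG01"]),
        "\t".join(["worked_pathway_b", "synthetic set",
                   "GWG02", "GWG03", "PRG02", "PRG03", "APP"]),
    ]

    components = {"P05067": {"platforms": ["proteomics"], "planted": False,
                             "fold_change": 2.37, "C": 4092, "H": 11294,
                             "role": "GOF", "true_score": 1.0}}
    truth = GroundTruth(planted=[], components=components, planted_pairs=[])
    tables = {
        "genetics": pd.DataFrame(gwas_rows),
        "epigenetics": pd.DataFrame(epi_rows, columns=["gene_symbol", "uniprot_id",
                                                       "direction", "pubmed_id"]),
        "proteomics": pd.DataFrame(prot_rows),
        "metabolomics": pd.DataFrame(met_rows),
        "links": pd.DataFrame(link_rows),
        "drugs": pd.DataFrame(drug_rows),
        "annotations": pd.DataFrame(ann_rows),
        "gene_map": pd.DataFrame(map_rows),
        "ppi_edges": pd.DataFrame(ppi_rows),
    }
    return Bundle(tables=tables, gmt_lines=gmt_lines, ground_truth=truth, config=None)
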