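"""Readers, writers and validated domain types for every table the pipeline touches.

The pipeline consumes hand-curated evidence tables (GWAS associations, epigenetic
events, CSF proteomic changes, metabolite changes), an HMDB-style metabolite->protein
link table, a TTD/DrugBank-style drug catalog, per-target pathogenesis annotations and
GMT pathway files.  Everything is delimited UTF-8 text with a required header, one
observation per row.  Validation is total: every input row is either accepted into the
typed table or reported (with its row number) in the ``rejected`` entry of the returned
frame's ``attrs``.

Fold-change convention
----------------------
Stored fold changes are signed magnitudes >= 1: positive when the analyte is higher in
cases, negative when lower.  Raw ratios ``r`` in (0, 1) (a halving reported as 0.5) are
converted to ``-1/r`` when ``auto_normalize`` is on (the default), because downstream
scoring consumes ``|F| >= 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Platform",
    "Stage",
    "Role",
    "Direction",
    "GeneticAssociation",
    "ProteomicChange",
    "MetaboliteChange",
    "EpigeneticEvent",
    "MetaboliteProteinLink",
    "DrugRecord",
    "PathogenesisAnnotation",
    "ScoringConfig",
    "PathwayGeneSets",
    "MODE_VOCABULARY",
    "load_moa_classes",
    "load_stage_synonyms",
    "read_evidence_bundle",
    "read_drug_catalog",
    "read_annotations",
    "read_gene_map",
    "read_gmt",
    "read_table",
    "write_network",
    "read_network",
]


class Platform(str, Enum):
    """Omics platform that implicates a candidate target."""

    genetics = "genetics"
    epigenetics = "epigenetics"
    proteomics = "proteomics"
    metabolomics = "metabolomics"


class Stage(str, Enum):
    approved = "approved"
    clinical_trial = "clinical_trial"
    experimental = "experimental"


class Role(str, Enum):
    """Gain- or loss-of-function role of a target in disease."""

    GOF = "GOF"
    LOF = "LOF"
    unknown = "unknown"


class Direction(str, Enum):
    hyper = "hyper"
    hypo = "hypo"
    altered = "altered"


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("adrepo.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_moa_classes(path: str | Path | None = None) -> dict[str, list[str]]:
    """Mode-of-action vocabulary partitioned into inhibiting/activating/neutral classes.

    A user file replaces the shipped one; it must define exactly these three keys.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) if path else _load_packaged_yaml("moa_classes.yaml")
    missing = {"inhibiting", "activating", "neutral"} - set(data)
    if missing:
        raise ValueError(f"mode-of-action class file missing classes: {sorted(missing)}")
    return {k: [str(t).lower() for t in v] for k, v in data.items()}


def load_stage_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Flat mapping from lowercase free-text stage to the canonical stage token."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) if path else _load_packaged_yaml("stage_synonyms.yaml")
    out: dict[str, str] = {}
    for canonical, synonyms in data.items():
        Stage(canonical)  # validate key
        for s in synonyms:
            out[str(s).lower().strip()] = canonical
    return out


MODE_VOCABULARY: frozenset[str] = frozenset(
    t for tokens in load_moa_classes().values() for t in tokens
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class GeneticAssociation(BaseModel):
    """One GWAS hit: a SNP associated with disease, with its per-allele odds ratio."""

    model_config = ConfigDict(frozen=True)

    gene_symbol: str
    snp_id: str = Field(min_length=1)
    odds_ratio: float = Field(gt=0)
    p_value: float = Field(gt=0, le=1)
    initial_n: int = Field(default=0, ge=0)
    replication_n: int = Field(default=0, ge=0)
    pubmed_id: str = ""


class ProteomicChange(BaseModel):
    """A CSF protein significantly altered in cases vs controls."""

    model_config = ConfigDict(frozen=True)

    uniprot_id: str = Field(min_length=1)
    gene_symbol: str = ""
    fold_change: float
    sample_type: Literal["CSF"] = "CSF"
    pubmed_id: str = ""

    @field_validator("fold_change")
    @classmethod
    def _magnitude(cls, v: float) -> float:
        if abs(v) < 1:
            raise ValueError(f"fold_change magnitude must be >= 1, got {v}")
        return v


class MetaboliteChange(BaseModel):
    """A metabolite significantly altered in cases vs controls."""

    model_config = ConfigDict(frozen=True)

    metabolite_id: str = Field(min_length=1)
    name: str = ""
    fold_change: float
    sample_type: str = ""

    @field_validator("fold_change")
    @classmethod
    def _magnitude(cls, v: float) -> float:
        if abs(v) < 1:
            raise ValueError(f"fold_change magnitude must be >= 1, got {v}")
        return v


class EpigeneticEvent(BaseModel):
    """A differential-methylation event at a gene; contributes platform membership only."""

    model_config = ConfigDict(frozen=True)

    gene_symbol: str = Field(min_length=1)
    uniprot_id: str = ""
    direction: Direction
    pubmed_id: str = ""


class MetaboliteProteinLink(BaseModel):
    """One edge of the HMDB-style metabolite-protein bipartite graph."""

    model_config = ConfigDict(frozen=True)

    metabolite_id: str = Field(min_length=1)
    uniprot_id: str = Field(min_length=1)


class DrugRecord(BaseModel):
    """A drug with its target, development stage and mode of action."""

    model_config = ConfigDict(frozen=True)

    drug_name: str = Field(min_length=1)
    target_uniprot: str = Field(min_length=1)
    stage: Stage
    mode_of_action: str
    original_indication: str = ""
    source_db: str = "other"

    @field_validator("mode_of_action")
    @classmethod
    def _vocab(cls, v: str) -> str:
        v = v.lower().strip()
        if v not in MODE_VOCABULARY:
            raise ValueError(f"mode_of_action {v!r} not in vocabulary")
        return v


class PathogenesisAnnotation(BaseModel):
    """GOF/LOF role plus the literature counts C (citations) and H (publications)."""

    model_config = ConfigDict(frozen=True)

    uniprot_id: str = Field(min_length=1)
    role: Role = Role.unknown
    citation_count: int = Field(default=0, ge=0)
    publication_count: int = Field(default=0, ge=0)


class ScoringConfig(BaseModel):
    """Weights and reference constants of the weighted-sum target score.

    The effect, citation and publication terms are weighted 0.33/0.34/0.33 and each
    component is normalized to an internal-control reference: the CSF Abeta42 fold
    change (2.37), the APOE-e4 odds ratio (3.7), and the citation/publication counts
    of the founding APP literature (4092 / 11294).  A target whose evidence sits
    exactly at every reference scores exactly 1.
    """

    model_config = ConfigDict(frozen=True)

    w_effect: float = 0.33
    w_citation: float = 0.34
    w_publication: float = 0.33
    f_ref: float = Field(default=2.37, gt=0)
    or_ref: float = Field(default=3.7, gt=0)
    c_ref: int = Field(default=4092, gt=0)
    h_ref: int = Field(default=11294, gt=0)

    @model_validator(mode="after")
    def _weights_sum(self) -> "ScoringConfig":
        total = self.w_effect + self.w_citation + self.w_publication
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        return cls(**(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8")


@dataclass(frozen=True)
class PathwayGeneSets:
    """Named gene sets plus the background universe for over-representation tests."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            extra = genes - self.universe
            if extra:
                raise ValueError(f"pathway {name!r} has genes outside the universe: {sorted(extra)[:5]}")


# ---------------------------------------------------------------------------
# Low-level delimited I/O
# ---------------------------------------------------------------------------


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited UTF-8 table as strings; delimiter inferred from extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), dtype=str,
                     keep_default_na=False, encoding="utf-8")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _check_columns(df: pd.DataFrame, required: Sequence[str], optional: Sequence[str],
                   path: Path) -> None:
    cols = set(df.columns)
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    unknown = sorted(cols - set(required) - set(optional))
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {unknown}")


_PLATFORM_SCHEMAS: dict[str, tuple[type[BaseModel], list[str], list[str], list[str]]] = {
    # platform -> (model, required columns, optional columns, dedup key)
    "genetics": (GeneticAssociation,
                 ["gene_symbol", "snp_id", "odds_ratio", "p_value"],
                 ["initial_n", "replication_n", "pubmed_id"],
                 ["gene_symbol", "snp_id"]),
    "epigenetics": (EpigeneticEvent,
                    ["gene_symbol", "direction"],
                    ["uniprot_id", "pubmed_id"],
                    ["gene_symbol", "direction"]),
    "proteomics": (ProteomicChange,
                   ["uniprot_id", "fold_change"],
                   ["gene_symbol", "sample_type", "pubmed_id"],
                   ["uniprot_id"]),
    "metabolomics": (MetaboliteChange,
                     ["metabolite_id", "fold_change"],
                     ["name", "sample_type"],
                     ["metabolite_id"]),
    "links": (MetaboliteProteinLink,
              ["metabolite_id", "uniprot_id"],
              [],
              ["metabolite_id", "uniprot_id"]),
}

_FOLD_PLATFORMS = {"proteomics", "metabolomics"}


def _normalize_fold(raw: str, auto_normalize: bool) -> tuple[float, bool]:
    """Apply the signed-magnitude fold-change convention.

    Returns (value, was_normalized).  Ratios with magnitude in (0, 1) become
    ``-1/|r|`` (a decrease) when normalization is on.
    """
    value = float(raw)
    if value == 0:
        raise ValueError("fold_change of 0 is undefined")
    if abs(value) < 1 and auto_normalize:
        return -1.0 / abs(value), True
    return value, False


def _validate_rows(df: pd.DataFrame, platform: str, auto_normalize: bool) -> pd.DataFrame:
    model, required, optional, key = _PLATFORM_SCHEMAS[platform]
    records: list[dict] = []
    rejected: list[tuple[int, str]] = []
    n_normalized = 0
    for i, row in enumerate(df.to_dict(orient="records")):
        payload = {k: v for k, v in row.items() if v != ""}
        try:
            if platform in _FOLD_PLATFORMS and "fold_change" in payload:
                payload["fold_change"], was = _normalize_fold(str(payload["fold_change"]), auto_normalize)
                n_normalized += was
            records.append(model(**payload).model_dump())
        except (ValidationError, ValueError) as exc:
            rejected.append((i + 2, _brief_error(exc)))  # +2: header line + 1-basing
    out = pd.DataFrame(records, columns=list(model.model_fields))
    if platform == "epigenetics" and not out.empty:
        out["direction"] = out["direction"].map(lambda d: d.value if isinstance(d, Direction) else d)
    before = len(out)
    out = out.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    n_dupes = before - len(out)
    if rejected:
        logger.warning("%s: rejected %d row(s): %s", platform, len(rejected), rejected[:5])
    if n_dupes:
        logger.warning("%s: dropped %d duplicate row(s) on key %s", platform, n_dupes, key)
    if n_normalized:
        logger.warning("%s: normalized %d sub-unity fold change(s) to -1/r", platform, n_normalized)
    out.attrs["rejected"] = rejected
    out.attrs["n_duplicates"] = n_dupes
    out.attrs["n_normalized"] = n_normalized
    return out


def _brief_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "row"
        return f"{loc}: {first['msg']}"
    return str(exc)


def read_evidence_bundle(paths: Mapping[str, str | Path], delimiter: str | None = None,
                         auto_normalize: bool = True) -> dict[str, pd.DataFrame]:
    """Read and validate every evidence table named in ``paths``.

    ``paths`` maps platform names (``genetics``, ``epigenetics``, ``proteomics``,
    ``metabolomics``, ``links``) to files.  Each returned frame carries a
    ``rejected`` list of ``(line_number, message)`` in ``.attrs``; duplicate rows on
    the platform key are dropped keeping the first occurrence.
    """
    bundle: dict[str, pd.DataFrame] = {}
    for platform, path in paths.items():
        if platform not in _PLATFORM_SCHEMAS:
            raise ValueError(f"unknown platform {platform!r}; expected one of {sorted(_PLATFORM_SCHEMAS)}")
        path = Path(path)
        raw = read_table(path, delimiter)
        model, required, optional, _ = _PLATFORM_SCHEMAS[platform]
        _check_columns(raw, required, optional, path)
        bundle[platform] = _validate_rows(raw, platform, auto_normalize)
    return bundle


def read_drug_catalog(path: str | Path, stage_synonyms: Mapping[str, str] | None = None,
                      delimiter: str | None = None) -> pd.DataFrame:
    """Read a TTD/DrugBank-style drug-target catalog.

    Free-text development stages are normalized through the synonym map (any
    ``phase ...`` string counts as a clinical trial); unmapped stages fall back to
    ``experimental`` with a warning.  Modes of action outside the shipped vocabulary
    fall back to ``unknown`` with a warning.
    """
    path = Path(path)
    raw = read_table(path, delimiter)
    _check_columns(raw, ["drug_name", "target_uniprot", "stage", "mode_of_action"],
                   ["original_indication", "source_db"], path)
    synonyms = dict(stage_synonyms) if stage_synonyms is not None else load_stage_synonyms()

    records, rejected = [], []
    n_stage_fallback = n_mode_fallback = 0
    for i, row in enumerate(raw.to_dict(orient="records")):
        stage_raw = str(row.get("stage", "")).lower().strip()
        stage = synonyms.get(stage_raw)
        if stage is None and stage_raw.startswith("phase"):
            stage = Stage.clinical_trial.value
        if stage is None:
            logger.warning("drug catalog line %d: unmapped stage %r -> experimental", i + 2, row.get("stage"))
            stage = Stage.experimental.value
            n_stage_fallback += 1
        mode = str(row.get("mode_of_action", "")).lower().strip()
        if mode not in MODE_VOCABULARY:
            logger.warning("drug catalog line %d: unknown mode of action %r -> unknown", i + 2, row.get("mode_of_action"))
            mode = "unknown"
            n_mode_fallback += 1
        payload = {k: v for k, v in row.items() if v != ""}
        payload["stage"], payload["mode_of_action"] = stage, mode
        try:
            rec = DrugRecord(**payload).model_dump()
            rec["stage"] = rec["stage"].value if isinstance(rec["stage"], Stage) else rec["stage"]
            records.append(rec)
        except ValidationError as exc:
            rejected.append((i + 2, _brief_error(exc)))
    out = pd.DataFrame(records, columns=list(DrugRecord.model_fields))
    out = out.drop_duplicates(subset=["drug_name", "target_uniprot", "mode_of_action"],
                              keep="first").reset_index(drop=True)
    if rejected:
        logger.warning("drug catalog: rejected %d row(s): %s", len(rejected), rejected[:5])
    out.attrs["rejected"] = rejected
    out.attrs["n_stage_fallback"] = n_stage_fallback
    out.attrs["n_mode_fallback"] = n_mode_fallback
    return out


def read_annotations(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read per-target pathogenesis annotations (GOF/LOF role, C and H counts)."""
    path = Path(path)
    raw = read_table(path, delimiter)
    _check_columns(raw, ["uniprot_id"], ["role", "citation_count", "publication_count"], path)
    records, rejected = [], []
    for i, row in enumerate(raw.to_dict(orient="records")):
        payload = {k: v for k, v in row.items() if v != ""}
        try:
            rec = PathogenesisAnnotation(**payload).model_dump()
            rec["role"] = rec["role"].value if isinstance(rec["role"], Role) else rec["role"]
            records.append(rec)
        except ValidationError as exc:
            rejected.append((i + 2, _brief_error(exc)))
    out = pd.DataFrame(records, columns=list(PathogenesisAnnotation.model_fields))
    out = out.drop_duplicates(subset=["uniprot_id"], keep="first").reset_index(drop=True)
    if rejected:
        logger.warning("annotations: rejected %d row(s): %s", len(rejected), rejected[:5])
    out.attrs["rejected"] = rejected
    return out


def read_gene_map(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a gene symbol -> UniProt accession mapping table (first mapping wins)."""
    raw = read_table(path, delimiter)
    _check_columns(raw, ["gene_symbol", "uniprot_id"], [], Path(path))
    mapping: dict[str, str] = {}
    for row in raw.itertuples(index=False):
        mapping.setdefault(row.gene_symbol, row.uniprot_id)
    return mapping


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayGeneSets:
    """Read a GMT file (set name, description, tab-separated member genes).

    The universe defaults to the union of all member genes; an explicit universe
    restricts every set to it (sets emptied by the restriction are dropped with a
    warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}")
        name, genes = fields[0], frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"{path}: line {lineno}: pathway {name!r} has no genes")
        sets[name] = genes
    if universe is not None:
        uni = frozenset(universe)
        kept: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            inside = genes & uni
            if not inside:
                logger.warning("pathway %r dropped: no genes inside the supplied universe", name)
                continue
            if inside != genes:
                logger.warning("pathway %r restricted to the supplied universe (%d -> %d genes)",
                               name, len(genes), len(inside))
            kept[name] = inside
        sets = kept
    else:
        uni = frozenset().union(*sets.values()) if sets else frozenset()
    return PathwayGeneSets(sets=sets, universe=uni)


# ---------------------------------------------------------------------------
# Network export/import (Cytoscape-compatible)
# ---------------------------------------------------------------------------

_SIF_RELATION = "links"


def _canonical_graph(graph: nx.Graph) -> nx.Graph:
    """Rebuild a graph with lexicographically sorted nodes and edges (deterministic I/O)."""
    out = nx.Graph(**graph.graph)
    for node in sorted(graph.nodes):
        out.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges):
        out.add_edge(u, v, **graph.edges[u, v])
    return out


def write_network(graph: nx.Graph, path: str | Path, format: str = "SIF") -> None:
    """Write a graph as SIF (one ``a links b`` line per edge) or GraphML.

    Node and edge order is lexicographic, so output bytes are deterministic.
    Isolated nodes appear as single-column SIF lines.
    """
    path = Path(path)
    graph = _canonical_graph(graph)
    fmt = format.upper()
    if fmt == "SIF":
        lines = [f"{u}\t{_SIF_RELATION}\t{v}" for u, v in graph.edges]
        lines += [str(n) for n in graph.nodes if graph.degree(n) == 0]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "GRAPHML":
        nx.write_graphml(graph, path, encoding="utf-8", named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r}; expected SIF or GraphML")


def read_network(path: str | Path, format: str = "SIF") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "SIF":
        graph = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                graph.add_node(fields[0])
            else:
                source, _, targets = fields[0], fields[1], fields[2:]
                for t in targets:
                    graph.add_edge(source, t)
        return graph
    if fmt == "GRAPHML":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {format!r}; expected SIF or GraphML")
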