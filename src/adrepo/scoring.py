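"""The weighted-sum target score and deterministic ranking.

A candidate target is scored from one evidence platform by a weighted sum of three
normalized components::

    TS = w_effect * (effect / effect_ref)
       + w_citation * (C / 4092)
       + w_publication * (H / 11294)

where the effect is the odds ratio of the risk allele (genetics, reference 3.7, the
APOE-e4 odds ratio), the absolute fold change of the protein in CSF (proteomics,
reference 2.37, the CSF Abeta42 fold change), or an imputed fold change (metabolomics);
C is the citation count of the paper establishing the target's pathogenic mechanism and
H the count of publications connecting the target to the disease.  Default weights are
0.33/0.34/0.33.  A target whose evidence sits exactly at every reference scores exactly
1, which is how the APP internal control anchors the scale; computed scores are not
capped and may exceed 1.

For metabolomics-derived targets the fold change is imputed from the target's linked
metabolites: the mean fold magnitude over all ``N`` metabolites linked to the protein,
with the ``N - n`` unchanged ones counted at magnitude 1 (no change)::

    imputed = (sum_i |F_i| + (N - n)) / N
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence_io import ScoringConfig

__all__ = [
    "ScoreBreakdown",
    "RankedTarget",
    "impute_metabolomic_fold",
    "score_genetic",
    "score_proteomic",
    "score_metabolomic",
    "score_target",
    "rank_targets",
    "score_targets",
    "ranked_to_frame",
    "write_ranked",
    "read_ranked",
    "SCOREABLE_PLATFORMS",
    "PRIORITY_ORDER",
]

SCOREABLE_PLATFORMS = ("genetics", "proteomics", "metabolomics")
#: platform preference under the ``priority`` resolution rule
PRIORITY_ORDER = ("proteomics", "genetics", "metabolomics")


@dataclass(frozen=True)
class ScoreBreakdown:
    """One target's score, split into its three weighted components."""

    uniprot_id: str
    platform_used: str
    effect_term: float
    citation_term: float
    publication_term: float
    total: float

    def __post_init__(self) -> None:
        if min(self.effect_term, self.citation_term, self.publication_term) < 0:
            raise ValueError("score terms must be non-negative")


@dataclass(frozen=True)
class RankedTarget:
    """A scored target with its dense rank; the internal control is pinned at 1."""

    uniprot_id: str
    platform_used: str
    effect_term: float
    citation_term: float
    publication_term: float
    total: float
    rank: int
    is_internal_control: bool = False


def _breakdown(uniprot_id: str, platform: str, effect_ratio: float,
               citations: float, publications: float, config: ScoringConfig) -> ScoreBreakdown:
    effect = config.w_effect * effect_ratio
    citation = config.w_citation * (citations / config.c_ref)
    publication = config.w_publication * (publications / config.h_ref)
    return ScoreBreakdown(
        uniprot_id=uniprot_id,
        platform_used=platform,
        effect_term=effect,
        citation_term=citation,
        publication_term=publication,
        total=math.fsum((effect, citation, publication)),
    )


def impute_metabolomic_fold(fold_magnitudes: Sequence[float], total_linked: int) -> float:
    """Impute a protein's fold change from its linked altered metabolites.

    ``fold_magnitudes`` holds ``|F_i|`` for the ``n`` altered metabolites linked to
    the protein; ``total_linked`` is ``N``, all distinct metabolites linked to it.
    The imputed value is the mean magnitude over all ``N`` links with the unchanged
    ``N - n`` counted as 1 (assumed unchanged): ``(sum |F_i| + N - n) / N``.
    """
    n = len(fold_magnitudes)
    if n == 0:
        raise ValueError("metabolomic fold imputation needs at least one altered metabolite")
    if total_linked < n:
        raise ValueError(f"total linked metabolites N={total_linked} < altered n={n}")
    mags = [abs(f) for f in fold_magnitudes]
    if min(mags) < 1:
        raise ValueError("fold magnitudes must be >= 1 (normalized convention)")
    return (math.fsum(mags) + (total_linked - n)) / total_linked


def score_genetic(or_value: float, citations: float, publications: float,
                  config: ScoringConfig | None = None, uniprot_id: str = "") -> ScoreBreakdown:
    """Score a genetics-derived target from its risk-allele odds ratio."""
    config = config or ScoringConfig()
    if or_value <= 0:
        raise ValueError(f"odds ratio must be > 0, got {or_value}")
    _check_counts(citations, publications)
    return _breakdown(uniprot_id, "genetics", or_value / config.or_ref,
                      citations, publications, config)


def score_proteomic(fold_change: float, citations: float, publications: float,
                    config: ScoringConfig | None = None, uniprot_id: str = "") -> ScoreBreakdown:
    """Score a proteomics-derived target from its (signed) CSF fold change."""
    config = config or ScoringConfig()
    magnitude = abs(fold_change)
    if magnitude < 1:
        raise ValueError(f"fold-change magnitude must be >= 1, got {fold_change}")
    _check_counts(citations, publications)
    return _breakdown(uniprot_id, "proteomics", magnitude / config.f_ref,
                      citations, publications, config)


def score_metabolomic(fold_magnitudes: Sequence[float], total_linked: int,
                      citations: float, publications: float,
                      config: ScoringConfig | None = None, uniprot_id: str = "") -> ScoreBreakdown:
    """Score a metabolomics-derived target via the imputed fold change."""
    config = config or ScoringConfig()
    _check_counts(citations, publications)
    imputed = impute_metabolomic_fold(fold_magnitudes, total_linked)
    return _breakdown(uniprot_id, "metabolomics", imputed / config.f_ref,
                      citations, publications, config)


def _check_counts(citations: float, publications: float) -> None:
    if citations < 0 or publications < 0:
        raise ValueError("citation and publication counts must be >= 0")


def score_target(target: Mapping, *,
                 or_by_target: Mapping[str, float] | None = None,
                 fold_by_target: Mapping[str, float] | None = None,
                 fold_by_metabolite: Mapping[str, float] | None = None,
                 annotation: Mapping | None = None,
                 config: ScoringConfig | None = None,
                 resolution: str = "max") -> ScoreBreakdown:
    """Score one assembled candidate, resolving multi-platform evidence to one score.

    ``target`` is a candidate row (``uniprot_id``, ``platforms``, and for
    metabolomics ``linked_changed_metabolites`` / ``total_linked_metabolites``).
    Evidence lookups supply the strongest odds ratio and fold change per accession
    and the fold change per metabolite.  ``resolution`` picks the reported platform
    when several are scoreable: ``max`` (highest score, default) or ``priority``
    (proteomics > genetics > metabolomics).  Epigenetic evidence never scores.
    """
    config = config or ScoringConfig()
    if resolution not in ("max", "priority"):
        raise ValueError(f"unknown resolution rule {resolution!r}")
    acc = target["uniprot_id"]
    platforms = set(target["platforms"])
    citations = float(annotation["citation_count"]) if annotation else 0.0
    publications = float(annotation["publication_count"]) if annotation else 0.0

    candidates: dict[str, ScoreBreakdown] = {}
    if "genetics" in platforms and or_by_target and acc in or_by_target:
        candidates["genetics"] = score_genetic(or_by_target[acc], citations, publications,
                                               config, uniprot_id=acc)
    if "proteomics" in platforms and fold_by_target and acc in fold_by_target:
        candidates["proteomics"] = score_proteomic(fold_by_target[acc], citations, publications,
                                                   config, uniprot_id=acc)
    if "metabolomics" in platforms:
        mets = list(target.get("linked_changed_metabolites", []))
        mags = [abs(fold_by_metabolite[m]) for m in mets
                if fold_by_metabolite and m in fold_by_metabolite]
        if mags:
            candidates["metabolomics"] = score_metabolomic(
                mags, int(target["total_linked_metabolites"]),
                citations, publications, config, uniprot_id=acc)

    if not candidates:
        raise ValueError(f"target {acc}: no scoreable platform "
                         f"(platforms={sorted(platforms)}; epigenetics alone never scores)")
    if resolution == "max":
        chosen = max(candidates.values(), key=lambda b: (b.total, b.platform_used))
    else:
        chosen = next(candidates[p] for p in PRIORITY_ORDER if p in candidates)
    return chosen


def rank_targets(breakdowns: Iterable[ScoreBreakdown],
                 internal_control: str | None = None) -> list[RankedTarget]:
    """Order scored targets by total descending (ties by accession ascending).

    If ``internal_control`` names an accession, its total is pinned to exactly 1.0
    (its computed terms are kept for inspection) and the row is flagged.  Ranks are
    dense from 1.
    """
    items = list(breakdowns)
    seen: set[str] = set()
    for b in items:
        if b.uniprot_id in seen:
            raise ValueError(f"duplicate accession in score list: {b.uniprot_id}")
        seen.add(b.uniprot_id)
    if internal_control is not None and internal_control not in seen and items:
        raise ValueError(f"internal control {internal_control!r} not among scored targets")

    def total_of(b: ScoreBreakdown) -> float:
        return 1.0 if b.uniprot_id == internal_control else b.total

    ordered = sorted(items, key=lambda b: (-total_of(b), b.uniprot_id))
    return [
        RankedTarget(
            uniprot_id=b.uniprot_id,
            platform_used=b.platform_used,
            effect_term=b.effect_term,
            citation_term=b.citation_term,
            publication_term=b.publication_term,
            total=total_of(b),
            rank=i + 1,
            is_internal_control=b.uniprot_id == internal_control,
        )
        for i, b in enumerate(ordered)
    ]


def score_targets(targets: pd.DataFrame,
                  genetic: pd.DataFrame | None = None,
                  proteomic: pd.DataFrame | None = None,
                  metabolomic: pd.DataFrame | None = None,
                  annotations: pd.DataFrame | None = None,
                  gene_map: Mapping[str, str] | None = None,
                  config: ScoringConfig | None = None,
                  resolution: str = "max",
                  internal_control: str | None = None) -> list[RankedTarget]:
    """Score and rank an assembled candidate table against its evidence tables.

    Per accession the strongest association (max odds ratio) and the largest fold
    magnitude are used.  Targets with no scoreable platform (epigenetics only, or
    evidence rows missing) are skipped.
    """
    config = config or ScoringConfig()
    gene_map = dict(gene_map or {})

    or_by_target: dict[str, float] = {}
    if genetic is not None and not genetic.empty:
        for row in genetic.itertuples(index=False):
            acc = gene_map.get(row.gene_symbol)
            if acc is None:
                continue
            value = float(row.odds_ratio)
            if value > or_by_target.get(acc, 0.0):
                or_by_target[acc] = value

    fold_by_target: dict[str, float] = {}
    if proteomic is not None and not proteomic.empty:
        for row in proteomic.itertuples(index=False):
            value = float(row.fold_change)
            if abs(value) > abs(fold_by_target.get(row.uniprot_id, 0.0)):
                fold_by_target[row.uniprot_id] = value

    fold_by_metabolite: dict[str, float] = {}
    if metabolomic is not None and not metabolomic.empty:
        fold_by_metabolite = {row.metabolite_id: float(row.fold_change)
                              for row in metabolomic.itertuples(index=False)}

    annotation_by_target: dict[str, dict] = {}
    if annotations is not None and not annotations.empty:
        annotation_by_target = {row.uniprot_id: row._asdict()
                                for row in annotations.itertuples(index=False)}

    breakdowns: list[ScoreBreakdown] = []
    skipped = 0
    for _, row in targets.iterrows():
        try:
            breakdowns.append(score_target(
                row, or_by_target=or_by_target, fold_by_target=fold_by_target,
                fold_by_metabolite=fold_by_metabolite,
                annotation=annotation_by_target.get(row["uniprot_id"]),
                config=config, resolution=resolution))
        except ValueError:
            skipped += 1
    if skipped:
        import logging
        logging.getLogger(__name__).info("%d target(s) had no scoreable platform and were skipped", skipped)
    control = internal_control if internal_control in {b.uniprot_id for b in breakdowns} else None
    return rank_targets(breakdowns, internal_control=control)


def ranked_to_frame(ranked: Sequence[RankedTarget],
                    gene_symbols: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tabulate a ranked-target list (accession, symbol, terms, total, rank, flag)."""
    gene_symbols = dict(gene_symbols or {})
    return pd.DataFrame([
        {
            "uniprot_id": r.uniprot_id,
            "gene_symbol": gene_symbols.get(r.uniprot_id, ""),
            "platform_used": r.platform_used,
            "effect_term": r.effect_term,
            "citation_term": r.citation_term,
            "publication_term": r.publication_term,
            "total": r.total,
            "rank": r.rank,
            "is_internal_control": r.is_internal_control,
        }
        for r in ranked
    ], columns=["uniprot_id", "gene_symbol", "platform_used", "effect_term",
                "citation_term", "publication_term", "total", "rank",
                "is_internal_control"])


def write_ranked(ranked: Sequence[RankedTarget], path: str | Path,
                 gene_symbols: Mapping[str, str] | None = None) -> None:
    ranked_to_frame(ranked, gene_symbols).to_csv(path, sep="\t", index=False)


def read_ranked(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"uniprot_id": str, "gene_symbol": str},
                     keep_default_na=False)
    if not df.empty:
        df["is_internal_control"] = df["is_internal_control"].astype(bool)
    return df
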