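"""Build the unified candidate-target list from the four omics platforms.

Metabolomics implicates a protein indirectly: a protein qualifies when it is linked
(HMDB-style) to at least ``min_links`` distinct disease-altered metabolites.  For each
such protein we track ``n`` (linked altered metabolites) and ``N`` (all distinct
metabolites linked to the protein anywhere in the link table); both feed the
metabolomic fold-change imputation downstream, which assumes unlinked-but-unchanged
metabolites have fold magnitude 1.

Candidate tables are plain DataFrames with columns::

    uniprot_id, gene_symbol, platforms (set of platform tokens),
    linked_changed_metabolites (sorted list), total_linked_metabolites (int)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "collect_metabolite_proteins",
    "assemble_targets",
    "multiplatform_targets",
    "write_targets",
    "read_targets",
]

TARGET_COLUMNS = ["uniprot_id", "gene_symbol", "platforms",
                  "linked_changed_metabolites", "total_linked_metabolites"]


def _empty_targets() -> pd.DataFrame:
    return pd.DataFrame(columns=TARGET_COLUMNS)


def collect_metabolite_proteins(links: pd.DataFrame, changes: pd.DataFrame,
                                min_links: int = 2) -> pd.DataFrame:
    """Proteins linked to >= ``min_links`` distinct altered metabolites.

    Parameters
    ----------
    links
        Metabolite->protein link table with ``metabolite_id`` and ``uniprot_id``.
    changes
        Altered-metabolite table with ``metabolite_id``.
    min_links
        Minimum number of distinct altered metabolites (default 2, the inclusion
        rule for metabolomics-derived targets).
    """
    if min_links < 1:
        raise ValueError(f"min_links must be >= 1, got {min_links}")
    if links.empty or changes.empty:
        return _empty_targets()
    links = links.drop_duplicates(subset=["metabolite_id", "uniprot_id"])
    changed = set(changes["metabolite_id"])
    absent = changed - set(links["metabolite_id"])
    if absent:
        logger.warning("%d altered metabolite(s) absent from the link table: %s",
                       len(absent), sorted(absent)[:5])

    rows = []
    for protein, group in links.groupby("uniprot_id", sort=True):
        partners = set(group["metabolite_id"])
        hit = sorted(partners & changed)
        if len(hit) >= min_links:
            rows.append({
                "uniprot_id": protein,
                "gene_symbol": "",
                "platforms": {"metabolomics"},
                "linked_changed_metabolites": hit,
                "total_linked_metabolites": len(partners),
            })
    return pd.DataFrame(rows, columns=TARGET_COLUMNS) if rows else _empty_targets()


def assemble_targets(genetic: pd.DataFrame | None = None,
                     epigenetic: pd.DataFrame | None = None,
                     proteomic: pd.DataFrame | None = None,
                     metabolite_targets: pd.DataFrame | None = None,
                     gene_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Merge per-platform hits into one candidate row per UniProt accession.

    GWAS and epigenetic rows report genes; they are resolved to accessions through
    ``gene_map`` (epigenetic rows may carry their own accession, which wins).
    Unmappable genes are dropped with a warning.  Output is sorted by accession and
    ``platforms`` is the union over contributing platforms.
    """
    gene_map = dict(gene_map or {})
    merged: dict[str, dict] = {}

    def upsert(acc: str, symbol: str, platform: str) -> None:
        entry = merged.setdefault(acc, {
            "uniprot_id": acc, "gene_symbol": "", "platforms": set(),
            "linked_changed_metabolites": [], "total_linked_metabolites": 0,
        })
        entry["platforms"].add(platform)
        if symbol and not entry["gene_symbol"]:
            entry["gene_symbol"] = symbol

    unmapped: set[str] = set()
    if genetic is not None and not genetic.empty:
        for row in genetic.itertuples(index=False):
            acc = gene_map.get(row.gene_symbol)
            if acc is None:
                unmapped.add(row.gene_symbol)
                continue
            upsert(acc, row.gene_symbol, "genetics")
    if epigenetic is not None and not epigenetic.empty:
        for row in epigenetic.itertuples(index=False):
            acc = getattr(row, "uniprot_id", "") or gene_map.get(row.gene_symbol)
            if not acc:
                unmapped.add(row.gene_symbol)
                continue
            upsert(acc, row.gene_symbol, "epigenetics")
    if proteomic is not None and not proteomic.empty:
        for row in proteomic.itertuples(index=False):
            upsert(row.uniprot_id, getattr(row, "gene_symbol", ""), "proteomics")
    if metabolite_targets is not None and not metabolite_targets.empty:
        for row in metabolite_targets.itertuples(index=False):
            upsert(row.uniprot_id, row.gene_symbol, "metabolomics")
            entry = merged[row.uniprot_id]
            entry["linked_changed_metabolites"] = list(row.linked_changed_metabolites)
            entry["total_linked_metabolites"] = int(row.total_linked_metabolites)
    if unmapped:
        logger.warning("%d gene symbol(s) without an accession mapping dropped: %s",
                       len(unmapped), sorted(unmapped)[:5])

    if not merged:
        return _empty_targets()
    symbol_of = {acc: sym for sym, acc in gene_map.items()}
    for acc, entry in merged.items():
        if not entry["gene_symbol"]:
            entry["gene_symbol"] = symbol_of.get(acc, "")
    rows = [merged[acc] for acc in sorted(merged)]
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def multiplatform_targets(targets: pd.DataFrame) -> pd.DataFrame:
    """Subset of candidates implicated by two or more platforms (same ordering)."""
    if targets.empty:
        return _empty_targets()
    mask = targets["platforms"].map(len) >= 2
    return targets.loc[mask].reset_index(drop=True)


def write_targets(targets: pd.DataFrame, path: str | Path) -> None:
    """Write a candidate table as TSV; platforms pipe-joined, metabolites comma-joined."""
    out = targets.copy()
    if not out.empty:
        out["platforms"] = out["platforms"].map(lambda s: "|".join(sorted(s)))
        out["linked_changed_metabolites"] = out["linked_changed_metabolites"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def read_targets(path: str | Path) -> pd.DataFrame:
    """Read a candidate table written by :func:`write_targets`."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        return _empty_targets()
    raw["platforms"] = raw["platforms"].map(lambda s: set(s.split("|")) if s else set())
    raw["linked_changed_metabolites"] = raw["linked_changed_metabolites"].map(
        lambda s: s.split(",") if s else [])
    raw["total_linked_metabolites"] = raw["total_linked_metabolites"].astype(int)
    return raw[TARGET_COLUMNS]
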