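"""Join ranked targets to the drug catalog and judge mechanistic compatibility.

Only approved or clinical-trial drugs are considered for repurposing.  A drug is
mechanistically compatible with a target when its mode of action opposes the target's
disease role: inhibiting modes (inhibitor, antagonist, antibody, ...) suit a
gain-of-function (GOF) target; activating modes (agonist, activator, ...) suit a
loss-of-function (LOF) target.  The opposite pairing is incompatible.  When either
the role or the direction class of the mode is unknown, compatibility is unknown.

Targets without pathogenesis information are excluded from the candidate table (they
remain in the ranked list).  Targets already established for the indication (by
default ACHE and APP) are labelled ``validation`` rather than ``novel``; recovering
them is the strategy's positive control.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence_io import load_moa_classes
from .scoring import RankedTarget, ranked_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "filter_stage",
    "assess_compatibility",
    "build_candidates",
    "summarize",
    "ELIGIBLE_STAGES",
    "DEFAULT_KNOWN_TARGETS",
]

ELIGIBLE_STAGES = ("approved", "clinical_trial")
DEFAULT_KNOWN_TARGETS = frozenset({"ACHE", "APP"})

CANDIDATE_COLUMNS = [
    "uniprot_id", "gene_symbol", "rank", "total", "drug_name", "stage",
    "mode_of_action", "compatibility", "category", "rationale_note",
]


def filter_stage(catalog: pd.DataFrame) -> pd.DataFrame:
    """Keep approved and clinical-trial drugs; drop experimental ones."""
    if catalog.empty:
        return catalog.copy()
    kept = catalog[catalog["stage"].isin(ELIGIBLE_STAGES)].reset_index(drop=True)
    logger.info("stage filter: kept %d of %d drug rows (%d approved, %d clinical)",
                len(kept), len(catalog),
                int((kept["stage"] == "approved").sum()),
                int((kept["stage"] == "clinical_trial").sum()))
    return kept


def _mode_class(mode: str, classes: Mapping[str, Sequence[str]]) -> str:
    mode = mode.lower().strip()
    for cls, tokens in classes.items():
        if mode in tokens:
            return cls
    raise ValueError(f"mode of action {mode!r} outside the vocabulary "
                     f"{sorted(t for ts in classes.values() for t in ts)}")


def assess_compatibility(role: str, mode_of_action: str,
                         classes: Mapping[str, Sequence[str]] | None = None) -> str:
    """Judge whether a drug's mode of action opposes the target's disease role.

    Returns ``compatible``, ``incompatible`` or ``unknown``.  ``unknown`` results
    exactly when the role is unknown or the mode belongs to the neutral (direction-
    less) class.
    """
    classes = classes or load_moa_classes()
    cls = _mode_class(mode_of_action, classes)
    if role not in ("GOF", "LOF", "unknown"):
        raise ValueError(f"unknown pathogenesis role {role!r}")
    if role == "unknown" or cls == "neutral":
        return "unknown"
    if (role == "GOF" and cls == "inhibiting") or (role == "LOF" and cls == "activating"):
        return "compatible"
    return "incompatible"


def build_candidates(ranked: Sequence[RankedTarget] | pd.DataFrame,
                     catalog: pd.DataFrame,
                     annotations: pd.DataFrame,
                     known_targets: Iterable[str] = DEFAULT_KNOWN_TARGETS,
                     classes: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """One row per (ranked target, eligible drug, mode) with a compatibility call.

    ``ranked`` may be a :func:`adrepo.scoring.rank_targets` result or its tabular
    form.  The catalog is stage-filtered here; targets absent from ``annotations``
    are excluded.  Rows are ordered by target rank then drug name.
    """
    classes = classes or load_moa_classes()
    known = {k.upper() for k in known_targets}
    ranked_df = ranked if isinstance(ranked, pd.DataFrame) else ranked_to_frame(ranked)
    eligible = filter_stage(catalog)
    if ranked_df.empty or eligible.empty or annotations.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    roles = {row.uniprot_id: row.role for row in annotations.itertuples(index=False)}
    rows = []
    for target in ranked_df.itertuples(index=False):
        role = roles.get(target.uniprot_id)
        if role is None:
            continue  # no pathogenesis information -> not a drug candidate
        drugs = eligible[eligible["target_uniprot"] == target.uniprot_id]
        for drug in drugs.itertuples(index=False):
            compatibility = assess_compatibility(role, drug.mode_of_action, classes)
            symbol = getattr(target, "gene_symbol", "") or target.uniprot_id
            rows.append({
                "uniprot_id": target.uniprot_id,
                "gene_symbol": symbol,
                "rank": int(target.rank),
                "total": float(target.total),
                "drug_name": drug.drug_name,
                "stage": drug.stage,
                "mode_of_action": drug.mode_of_action,
                "compatibility": compatibility,
                "category": "validation" if symbol.upper() in known else "novel",
                "rationale_note": f"{role} target + {drug.mode_of_action} -> {compatibility}",
            })
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if out.empty:
        return out
    out = out.drop_duplicates(subset=["uniprot_id", "drug_name", "mode_of_action"])
    out = out.sort_values(["rank", "drug_name"]).reset_index(drop=True)
    logger.info("drug candidates: %d pairs across %d target(s)",
                len(out), out["uniprot_id"].nunique())
    return out


def summarize(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-target drug counts, split by development stage and compatibility call."""
    columns = ["uniprot_id", "gene_symbol", "rank", "total", "n_drugs",
               "n_approved", "n_clinical_trial",
               "n_compatible", "n_incompatible", "n_unknown", "category"]
    if candidates.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for acc, group in candidates.groupby("uniprot_id", sort=False):
        dedup = group.drop_duplicates(subset=["drug_name"])
        first = group.iloc[0]
        rows.append({
            "uniprot_id": acc,
            "gene_symbol": first["gene_symbol"],
            "rank": int(first["rank"]),
            "total": float(first["total"]),
            "n_drugs": len(dedup),
            "n_approved": int((group["stage"] == "approved").sum()),
            "n_clinical_trial": int((group["stage"] == "clinical_trial").sum()),
            "n_compatible": int((group["compatibility"] == "compatible").sum()),
            "n_incompatible": int((group["compatibility"] == "incompatible").sum()),
            "n_unknown": int((group["compatibility"] == "unknown").sum()),
            "category": first["category"],
        })
    return pd.DataFrame(rows, columns=columns).sort_values("rank").reset_index(drop=True)
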