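"""Hypergeometric over-representation testing with Benjamini-Hochberg correction.

An in-house equivalent of the usual web-based pathway over-representation step: for a
query gene set of size ``n`` drawn from a universe of ``N_u`` genes, the probability
of overlapping a ``K``-gene pathway by at least the observed ``k`` genes is the upper
tail of the hypergeometric distribution.  P-values across pathways are adjusted by the
Benjamini-Hochberg step-up procedure (one-sided over-representation only; depletion is
not tested).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .evidence_io import PathwayGeneSets

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "bh_adjust", "enrich"]

RESULT_COLUMNS = ["pathway", "k", "K", "n", "N_u", "p_value", "adjusted_p",
                  "significant", "overlap_genes"]


def hypergeom_upper_tail(k: int, K: int, n: int, N_u: int) -> float:
    """Exact ``P(X >= k)`` for ``X ~ Hypergeometric(N_u, K, n)``.

    ``k`` observed overlap, ``K`` pathway size, ``n`` query size, ``N_u`` universe
    size.  ``k = 0`` is the certain event.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > N_u or n > N_u:
        raise ValueError(f"set sizes K={K}, n={n} exceed universe N_u={N_u}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N_u, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving and capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        bad = p[(p <= 0) | (p > 1)]
        raise ValueError(f"p-values outside (0, 1]: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query_genes: Iterable[str], gene_sets: PathwayGeneSets,
           alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation test of a query gene set against every pathway.

    Query genes outside the universe are dropped with a warning; an empty query
    after the intersection is an error.  Only pathways with overlap ``k >= 1`` are
    reported; BH adjustment runs across those.  Rows are sorted by adjusted p-value
    then pathway name, with ``significant = adjusted_p < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    query = set(query_genes)
    outside = query - gene_sets.universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped: %s",
                       len(outside), sorted(outside)[:5])
    query &= gene_sets.universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N_u, n = len(gene_sets.universe), len(query)
    rows = []
    for name in sorted(gene_sets.sets):
        genes = gene_sets.sets[name]
        overlap = query & genes
        if not overlap:
            continue
        rows.append({
            "pathway": name,
            "k": len(overlap),
            "K": len(genes),
            "n": n,
            "N_u": N_u,
            "p_value": hypergeom_upper_tail(len(overlap), len(genes), n, N_u),
            "overlap_genes": ",".join(sorted(overlap)),
        })
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"])
    out["significant"] = out["adjusted_p"] < alpha
    out = out.sort_values(["adjusted_p", "pathway"]).reset_index(drop=True)
    return out[RESULT_COLUMNS]
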