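"""Hypergeometric over-representation of a query gene list in gene sets.

For a universe of N genes, a set with m members in the universe, and a query
of q genes with k members in the set, the one-sided enrichment p-value is the
upper hypergeometric tail P(X >= k), and fold enrichment is (k/q) / (m/N).
p-values are adjusted across sets with the Benjamini-Hochberg step-up.
"""
from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["overrepresentation"]


def overrepresentation(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """One row per gene set: overlap, sizes, fold enrichment, p and BH q.

    Query genes outside the universe are dropped with a warning; an empty
    query after that intersection is an error.  Enrichment is one-sided
    (over-representation only).  Rows are ordered by p-value, ties by set
    name.
    """
    universe_list = list(dict.fromkeys(universe))
    uni = set(universe_list)
    n_universe = len(uni)
    query_list = list(dict.fromkeys(query))
    dropped = [g for g in query_list if g not in uni]
    if dropped:
        logger.warning(
            "%d query gene(s) outside the universe, dropped: %s",
            len(dropped),
            dropped[:5],
        )
    query_in = [g for g in query_list if g in uni]
    if not query_in:
        raise ValidationError("query is empty after intersection with universe")
    q = len(query_in)
    qset = set(query_in)

    rows = []
    for s in sets:
        members = set(s.genes) & uni
        m = len(members)
        k = len(members & qset)
        if m == 0:
            p = 1.0
            fold = float("nan")
        else:
            p = float(stats.hypergeom.sf(k - 1, n_universe, m, q))
            fold = (k / q) / (m / n_universe)
        rows.append(
            {
                "set": s.name,
                "overlap": k,
                "query_size": q,
                "set_size": m,
                "universe_size": n_universe,
                "fold_enrichment": fold,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return (
        table.sort_values(["p_value", "set"], kind="mergesort")
        .reset_index(drop=True)
    )
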