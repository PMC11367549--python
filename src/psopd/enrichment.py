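"""Over-representation analysis (hypergeometric tail) against GMT sets.

Given a query gene list and a background universe, each term's overlap is
scored with the one-sided hypergeometric tail P(X >= k) and terms are
Benjamini-Hochberg adjusted and sorted by (adjusted p, term name).
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import pandas as pd
from scipy.stats import hypergeom

from .genesets import GeneSetCollection
from .stats import adjust_fdr

logger = logging.getLogger(__name__)

__all__ = ["ora", "term_gene_network"]


def ora(
    query_genes: Sequence[str],
    universe: Sequence[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each term.

    Query genes outside the universe are dropped with a warning. Returns a
    DataFrame with columns ``term, k, K, n, N, p, fdr, significant, genes``
    (overlapping ids, sorted, pipe-joined), ordered by (fdr, p, term).
    An empty query yields an empty table.
    """
    uni = sorted(set(universe))
    uni_set = set(uni)
    query = sorted(set(query_genes))
    outside = [g for g in query if g not in uni_set]
    if outside:
        logger.warning("%d query genes outside the universe dropped (e.g. %s)",
                       len(outside), outside[:3])
    query = [g for g in query if g in uni_set]
    cols = ["term", "k", "K", "n", "N", "p", "fdr", "significant", "genes"]
    if len(query) == 0:
        return pd.DataFrame(columns=cols)
    n, N = len(query), len(uni)
    rows: List[Tuple] = []
    for term, members in collection:
        members_in = sorted(set(members) & uni_set)
        K = len(members_in)
        if K < min_set_size:
            continue
        overlap = sorted(set(members_in) & set(query))
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append((term, k, K, n, N, p, "|".join(overlap)))
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "genes"])
    table["fdr"] = adjust_fdr(table["p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["fdr", "p", "term"], kind="stable").reset_index(drop=True)[cols]


def term_gene_network(result: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Bipartite (term, gene) edge list for the ``top_n`` best-ranked terms.

    Edge count equals the summed overlap of the selected terms; ordering is
    deterministic (terms by rank, genes alphabetically).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(result) == 0:
        raise ValueError("enrichment result is empty")
    top = result.head(top_n)
    edges = []
    for _, row in top.iterrows():
        genes = [g for g in str(row["genes"]).split("|") if g]
        for g in genes:
            edges.append((row["term"], g))
    return pd.DataFrame(edges, columns=["term", "gene"])
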