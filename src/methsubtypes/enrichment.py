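"""Hypergeometric gene-set enrichment (generic TF-target sets via GMT).

For each named set the enrichment p-value is the upper hypergeometric
tail P(X >= overlap) with population = universe size, successes = set
size, draws = query size, followed by Benjamini-Hochberg adjustment
across sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection
from .screening import bh_fdr

logger = logging.getLogger(__name__)


def hypergeom_enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Enrichment of a query gene list against every set in the collection.

    Query genes outside the universe are dropped (reported via warning);
    an empty query after restriction raises.  Returns a frame indexed by
    set name with columns set_size, overlap, p, q, sorted by p.
    """
    query = set(query)
    dropped = query - collection.universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped: %s...",
                       len(dropped), sorted(dropped)[:5])
    query &= collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")

    M = len(collection.universe)
    N = len(query)
    rows = []
    for name, genes in sorted(collection.sets.items()):
        genes = genes & collection.universe
        n = len(genes)
        overlap = len(genes & query)
        # P(X >= overlap); overlap 0 gives p = 1 exactly
        p = float(hypergeom.sf(overlap - 1, M, n, N))
        rows.append((name, n, overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]
                       ).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort")
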