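"""Gene-set over-representation of the GBA-correlated PCG lists.

A plain one-sided (upper-tail) hypergeometric test of each gene set against
a query list within a fixed universe, with a raw-p significance rule at
alpha = 0.05 and an informational BH-adjusted column.  The universe
defaults to the PCGs measured in the expression matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_adjust
from .data_io import GeneSetCollection
from .errors import InputError
from .gba import SurrogateSet

logger = logging.getLogger(__name__)

_COLUMNS = ["set_name", "overlap", "query_size", "set_size", "universe_size",
            "p_value", "adj_p", "significant", "overlap_genes"]


def hypergeom_enrich(query, sets: GeneSetCollection, universe,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each set in the query.

    With universe size N, set size K (after intersection with the
    universe), query size n and overlap x, p = P(X >= x) for
    X ~ Hypergeom(N, K, n).  Sets with empty intersection are skipped.
    Rows are sorted by p ascending (ties by set name); ``significant``
    flags raw p < alpha.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise InputError(
            f"query genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for name in sets.names:
        members = set(sets[name]) & universe
        if not members:
            continue
        overlap = query & members
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(universe),
                                     len(members), len(query)))
        rows.append({
            "set_name": name,
            "overlap": len(overlap),
            "query_size": len(query),
            "set_size": len(members),
            "universe_size": len(universe),
            "p_value": min(p, 1.0),
            "overlap_genes": ",".join(sorted(overlap)),
        })
    if not rows:
        return pd.DataFrame(columns=_COLUMNS)
    frame = pd.DataFrame(rows)
    frame["adj_p"] = bh_adjust(frame["p_value"].to_numpy())
    frame["significant"] = frame["p_value"] < alpha
    frame = frame.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return frame[_COLUMNS]


def enrich_all_clusters(surrogates: SurrogateSet, sets: GeneSetCollection,
                        universe, alpha: float = 0.05
                        ) -> dict[tuple[int, str], pd.DataFrame]:
    """Enrichment of each cluster's up- and down-PCG lists separately."""
    out: dict[tuple[int, str], pd.DataFrame] = {}
    for cs in surrogates:
        for direction, frame in (("up", cs.up_pcgs), ("down", cs.down_pcgs)):
            if frame.empty:
                logger.info("cluster %d: empty %s-PCG list, skipping enrichment",
                            cs.cluster, direction)
                out[(cs.cluster, direction)] = pd.DataFrame(columns=_COLUMNS)
                continue
            out[(cs.cluster, direction)] = hypergeom_enrich(
                frame.index, sets, universe, alpha)
    return out
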