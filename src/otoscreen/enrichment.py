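"""Hypergeometric over-representation of DEGs in gene sets.

For a universe of N genes containing n DEGs, a set of K genes with k DEG
members is scored with the upper-tail hypergeometric probability P[X >= k].
Sets are ranked by BH-adjusted enrichment FDR, and a set becomes an eligible
connectivity query when its member DEGs include at least ``min_up``
up-regulated and ``min_down`` down-regulated genes (3 and 3 by default); the
query submitted downstream is exactly that pathway's member DEGs.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
from scipy import stats

from .deg import bh_fdr
from .types import SignedGeneSet, normalize_gene

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_id", "k", "K", "n", "N", "p", "q",
                      "member_up", "member_down"]


def enrich(
    degs: SignedGeneSet,
    sets: Mapping[str, frozenset],
    universe: frozenset,
) -> pd.DataFrame:
    """Score every gene set for DEG over-representation.

    Sets are intersected with the universe first; sets with fewer than two
    in-universe members are skipped with a log entry. DEGs outside the
    universe are an error (silent dropping would corrupt the counts).
    Records are sorted by q, then p, then set ID.
    """
    universe = frozenset(normalize_gene(g) for g in universe)
    if not universe:
        raise ValueError("empty universe")
    stray = (degs.up | degs.down) - universe
    if stray:
        raise ValueError(f"DEGs not in universe: {sorted(stray)[:5]}")
    deg_all = degs.up | degs.down
    N, n = len(universe), len(deg_all)

    rows = []
    for set_id, members in sets.items():
        in_univ = frozenset(normalize_gene(g) for g in members) & universe
        if len(in_univ) < 2:
            logger.info("set %s skipped: <2 in-universe members", set_id)
            continue
        member_up = in_univ & degs.up
        member_down = in_univ & degs.down
        k = len(member_up) + len(member_down)
        K = len(in_univ)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0), "member_up": member_up,
                     "member_down": member_down})
    records = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q"])
    if len(records):
        records["q"] = bh_fdr(records["p"].to_numpy())
        records = records.sort_values(["q", "p", "set_id"], kind="stable")
    else:
        records["q"] = []
    return records.reset_index(drop=True)[ENRICHMENT_COLUMNS]


def top_sets(records: pd.DataFrame, limit: int = 30) -> pd.DataFrame:
    """The ``limit`` best-ranked sets (all of them if fewer were tested)."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return records.head(limit).reset_index(drop=True)


def eligible_queries(
    records: pd.DataFrame,
    min_up: int = 3,
    min_down: int = 3,
) -> list[tuple[str, SignedGeneSet]]:
    """Connectivity queries from pathways with enough signed member DEGs.

    One query per record whose member DEGs include at least ``min_up`` up- and
    ``min_down`` down-regulated genes; the query is those member DEGs.
    """
    queries = []
    for row in records.itertuples(index=False):
        if len(row.member_up) >= min_up and len(row.member_down) >= min_down:
            queries.append((row.set_id, SignedGeneSet(up=frozenset(row.member_up),
                                                      down=frozenset(row.member_down))))
    return queries
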