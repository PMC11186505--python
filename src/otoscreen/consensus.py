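"""Aggregation of per-pathway connectivity hits into drug rankings.

A "hit" is a drug surviving the overlap-score cutoff within one pathway's
top-K connectivity list. Pathways with at least ``min_pathway_hits`` distinct
hit drugs are retained; drugs hitting multiple retained pathways are
prioritized; arms (independent datasets/comparisons) are merged into a
consensus table; and the per-arm query/perturbation bookkeeping is tallied.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

PATHWAY_HIT_COLUMNS = ["pathway_id", "n_hits", "hit_drugs", "retained"]
CONSENSUS_COLUMNS = ["drug_id", "arms", "n_arms", "pathways", "n_pathways",
                     "best_score", "annotation"]


def count_pathway_hits(
    results_by_pathway: Mapping[str, pd.DataFrame],
    min_hits: int = 3,
) -> pd.DataFrame:
    """Distinct hit drugs per pathway, with the >= min_hits retention flag.

    ``results_by_pathway`` maps pathway ID to its already score-filtered
    connectivity results. Sorted by hit count descending, pathway ID ascending.
    """
    rows = []
    for pathway_id, results in results_by_pathway.items():
        drugs = frozenset(results["drug_id"]) if len(results) else frozenset()
        rows.append({"pathway_id": pathway_id, "n_hits": len(drugs),
                     "hit_drugs": drugs, "retained": len(drugs) >= min_hits})
    table = pd.DataFrame(rows, columns=PATHWAY_HIT_COLUMNS)
    if len(table):
        table = table.sort_values(["n_hits", "pathway_id"],
                                  ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def multi_pathway_drugs(
    results_by_pathway: Mapping[str, pd.DataFrame],
    min_pathways: int = 2,
    min_hits: int = 3,
) -> pd.DataFrame:
    """Drugs hitting at least ``min_pathways`` distinct retained pathways.

    Sorted by pathway count descending, best score descending, drug ID.
    """
    hits = count_pathway_hits(results_by_pathway, min_hits=min_hits)
    retained = set(hits.loc[hits["retained"], "pathway_id"])
    per_drug: dict[str, dict] = {}
    for pathway_id, results in results_by_pathway.items():
        if pathway_id not in retained:
            continue
        for row in results.itertuples(index=False):
            entry = per_drug.setdefault(row.drug_id,
                                        {"pathways": set(), "best_score": float("-inf")})
            entry["pathways"].add(pathway_id)
            entry["best_score"] = max(entry["best_score"], row.score)
    rows = [
        {"drug_id": drug, "pathways": frozenset(e["pathways"]),
         "n_pathways": len(e["pathways"]), "best_score": e["best_score"]}
        for drug, e in per_drug.items() if len(e["pathways"]) >= min_pathways
    ]
    table = pd.DataFrame(rows, columns=["drug_id", "pathways", "n_pathways",
                                        "best_score"])
    if len(table):
        table = table.sort_values(["n_pathways", "best_score", "drug_id"],
                                  ascending=[False, False, True], kind="stable")
    return table.reset_index(drop=True)


def consensus_across_arms(
    per_arm: Mapping[str, Mapping[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Merge score-filtered results of several arms into one consensus table.

    ``per_arm`` maps arm ID -> {pathway ID -> filtered results}. Each drug
    carries the arms it appears in, its pooled pathway set, and its best score
    anywhere; sorted by arm count, then pathway count, then drug ID. The free
    ``annotation`` column is left empty for downstream curation.
    """
    if not per_arm:
        raise ValueError("need at least one arm")
    per_drug: dict[str, dict] = {}
    for arm_id, results_by_pathway in per_arm.items():
        for pathway_id, results in results_by_pathway.items():
            for row in results.itertuples(index=False):
                entry = per_drug.setdefault(
                    row.drug_id,
                    {"arms": set(), "pathways": set(), "best_score": float("-inf")})
                entry["arms"].add(arm_id)
                entry["pathways"].add(pathway_id)
                entry["best_score"] = max(entry["best_score"], row.score)
    rows = [
        {"drug_id": drug, "arms": frozenset(e["arms"]), "n_arms": len(e["arms"]),
         "pathways": frozenset(e["pathways"]), "n_pathways": len(e["pathways"]),
         "best_score": e["best_score"], "annotation": ""}
        for drug, e in per_drug.items()
    ]
    table = pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)
    if len(table):
        table = table.sort_values(["n_arms", "n_pathways", "drug_id"],
                                  ascending=[False, False, True], kind="stable")
    return table.reset_index(drop=True)


def tally(per_arm: Mapping[str, Mapping[str, pd.DataFrame]]) -> dict:
    """Bookkeeping: queries and returned perturbations per arm, plus totals.

    ``per_arm`` maps arm ID -> {query/pathway ID -> (unfiltered) top-K
    connectivity results}; the perturbation count of an arm is the sum of
    returned-result counts over its queries.
    """
    n_queries = {arm: len(results) for arm, results in per_arm.items()}
    n_perturbations = {
        arm: int(sum(len(res) for res in results.values()))
        for arm, results in per_arm.items()
    }
    return {
        "n_queries_per_arm": n_queries,
        "n_perturbations_per_arm": n_perturbations,
        "total_queries": int(sum(n_queries.values())),
        "total_perturbations": int(sum(n_perturbations.values())),
    }
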