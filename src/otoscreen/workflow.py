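"""End-to-end composition of the screening stages on one dataset arm.

An "arm" is one two-condition comparison: its expression matrix is reduced to
DEGs, gene sets are tested for enrichment, pathways passing the 3-up/3-down
rule seed connectivity queries, and each query returns a ranked top-K list of
drug perturbations. The per-arm results feed the consensus and tally stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import connectivity, deg, enrichment
from .config import PipelineConfig
from .types import SignatureCompendium, SignedGeneSet


@dataclass
class ArmResult:
    """Everything one arm produces on its way to the consensus stage."""

    deg_table: pd.DataFrame
    degs: SignedGeneSet
    enrichment_table: pd.DataFrame
    queries: list
    results_by_pathway: dict = field(default_factory=dict)   # unfiltered top-K
    filtered_by_pathway: dict = field(default_factory=dict)  # score > cutoff


def run_arm(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    gene_sets: Mapping[str, frozenset],
    compendium: SignatureCompendium,
    mode: str = "reverse",
    scoring: str = "overlap",
    regime: str = "array",
    config: PipelineConfig = None,
) -> ArmResult:
    """Run one arm from expression matrix to per-pathway connectivity results."""
    config = config or PipelineConfig()
    table = deg.compute_deg_stats(matrix, design)
    degs = deg.filter_degs(table, regime=regime, config=config)
    table = deg.annotate_directions(table, degs)
    universe = frozenset(matrix.index)
    records = enrichment.enrich(degs, gene_sets, universe)
    queries = enrichment.eligible_queries(records,
                                          min_up=config.query.min_up,
                                          min_down=config.query.min_down)
    results_by_pathway = {}
    filtered_by_pathway = {}
    for query in queries:
        res = connectivity.query_compendium(query, compendium, mode=mode,
                                            scoring=scoring,
                                            top_k=config.query.top_k)
        results_by_pathway[query[0]] = res
        filtered_by_pathway[query[0]] = connectivity.filter_by_score(
            res, cutoff=config.query.score_cutoff)
    return ArmResult(deg_table=table, degs=degs, enrichment_table=records,
                     queries=queries, results_by_pathway=results_by_pathway,
                     filtered_by_pathway=filtered_by_pathway)
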