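"""Differential-expression statistics and threshold-based DEG selection.

Two threshold regimes are supported, matching the two kinds of source data the
screen consumes: the "array" regime (|logFC| > 2 and P < 0.05, for microarray
and bulk RNA-seq comparisons) and the "scrna" regime (linear |FC| > 1.2 and
FDR q < 0.05, for precomputed single-cell DEG tables).

Per-gene statistics use a two-sample unequal-variance (Welch) t-test on log2
intensities; precomputed DEG tables with (gene, logfc, p, q) columns can enter
directly at :func:`filter_degs`.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import DegThresholds, PipelineConfig
from .types import SignedGeneSet, normalize_gene

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "logfc", "p", "q", "direction"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the p-sorted list, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compute_deg_stats(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    treated: str = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test statistics for a two-group log2 matrix.

    ``design`` maps sample (column) names to exactly two group labels.
    logFC is mean(treated) - mean(control); ``treated`` defaults to the
    non-"control" label when one label is literally "control", otherwise the
    lexicographically first label. Genes with zero variance and equal means in
    both groups get p = 1 (noted in the log). q is BH-adjusted over all genes.
    """
    design = {str(s): str(g) for s, g in design.items()}
    missing = [s for s in design if s not in matrix.columns]
    if missing:
        raise ValueError(f"design samples not in matrix: {missing[:5]}")
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if treated is None:
        treated = groups[0] if groups[1] == "control" else (
            groups[1] if groups[0] == "control" else groups[0])
    if treated not in groups:
        raise ValueError(f"treated label {treated!r} not among groups {groups}")
    control = groups[0] if treated == groups[1] else groups[1]

    a_cols = [s for s, g in design.items() if g == treated]
    b_cols = [s for s, g in design.items() if g == control]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >=2 samples for a t-test")

    a = matrix[a_cols].to_numpy(dtype=float)
    b = matrix[b_cols].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d gene(s) with zero variance in both groups; p set to 1",
                    int(degenerate.sum()))
        p[degenerate] = 1.0

    records = pd.DataFrame({
        "gene": [normalize_gene(g) for g in matrix.index],
        "logfc": logfc,
        "p": p,
        "q": bh_fdr(p),
        "direction": "none",
    })
    return records


def filter_degs(
    records: pd.DataFrame,
    regime: str = "array",
    config: PipelineConfig | DegThresholds = None,
) -> SignedGeneSet:
    """Apply one of the two published threshold regimes to a DEG table.

    array regime: |logfc| > logfc_cut and p < p_cut.
    scrna regime: linear |FC| > fc_cut_linear (|logfc| > log2(fc_cut_linear))
    and q < q_cut; records without a q value are rejected, not imputed.
    """
    thresholds = config.deg if isinstance(config, PipelineConfig) else config
    if thresholds is None:
        thresholds = DegThresholds()
    logfc = records["logfc"].to_numpy(dtype=float)
    if regime == "array":
        p = records["p"].to_numpy(dtype=float)
        keep = (np.abs(logfc) > thresholds.logfc_cut) & (p < thresholds.p_cut)
    elif regime == "scrna":
        q = records["q"].to_numpy(dtype=float)
        n_missing = int(np.isnan(q).sum())
        if n_missing:
            logger.warning("%d record(s) without q rejected under scrna regime",
                           n_missing)
        cut = np.log2(thresholds.fc_cut_linear)
        keep = (np.abs(logfc) > cut) & (q < thresholds.q_cut)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    genes = records["gene"].astype(str)
    up = frozenset(genes[keep & (logfc > 0)])
    down = frozenset(genes[keep & (logfc < 0)])
    return SignedGeneSet(up=up, down=down)


def annotate_directions(records: pd.DataFrame, degs: SignedGeneSet) -> pd.DataFrame:
    """Return a copy of the table with the direction column filled in."""
    out = records.copy()
    gene = out["gene"].map(normalize_gene)
    out["direction"] = np.where(gene.isin(degs.up), "up",
                                np.where(gene.isin(degs.down), "down", "none"))
    return out


def rank_degs(records: pd.DataFrame) -> pd.DataFrame:
    """Report order: p ascending, |logfc| descending, gene ID as tie-break."""
    out = records.copy()
    out["_abs"] = out["logfc"].abs()
    out = out.sort_values(["p", "_abs", "gene"], ascending=[True, False, True],
                          kind="stable").drop(columns="_abs")
    return out.reset_index(drop=True)
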