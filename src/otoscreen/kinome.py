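"""Kinase peptide-array analysis: slopes, QC, fold changes, and KRSA z-scores.

Raw chip reads are per-peptide fluorescence intensities at increasing camera
exposure times; the ordinary-least-squares slope of intensity vs exposure is
the peptide's activity. Peptides that look inactive (max signal <= min_signal)
or non-linear (R^2 < min_r2) are excluded. Case/control slope ratios outside
(fc_lo, fc_hi) mark a peptide as differentially phosphorylated. Upstream
kinases are then scored by random-sampling enrichment: the observed number of
differential peptides mapped to a kinase is z-scored against resampled random
peptide sets of the same size, chip by chip, and z is averaged across chips.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import KinomeChipRun

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-12  # degenerate null distributions report z = 0

ACTIVITY_COLUMNS = ["peptide_id", "slope", "r2", "max_signal"]


def fit_peptide_slopes(run: KinomeChipRun) -> pd.DataFrame:
    """OLS slope and R^2 of intensity vs exposure time for every peptide.

    A zero-variance (constant) response has slope 0 and, by convention,
    R^2 = 0. Columns: peptide_id, slope (intensity/ms), r2, max_signal.
    """
    x = run.exposures
    y = run.intensities.to_numpy(dtype=float)
    x_c = x - x.mean()
    y_c = y - y.mean(axis=1, keepdims=True)
    sxx = float(np.dot(x_c, x_c))
    sxy = y_c @ x_c
    slope = sxy / sxx
    ss_tot = (y_c ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, (sxy ** 2) / (sxx * ss_tot), 0.0)
    return pd.DataFrame({
        "peptide_id": run.peptides,
        "slope": slope,
        "r2": r2,
        "max_signal": y.max(axis=1),
    })


def qc_filter(
    activities: pd.DataFrame,
    min_signal: float = 5.0,
    min_r2: float = 0.90,
) -> pd.DataFrame:
    """Retain peptides with max_signal > min_signal and r2 >= min_r2.

    Peptides at or below ``min_signal`` count as inactive; fits below
    ``min_r2`` count as non-linear. Exclusions are logged with their reason.
    """
    inactive = activities["max_signal"] <= min_signal
    nonlinear = activities["r2"] < min_r2
    for row in activities[inactive].itertuples(index=False):
        logger.info("peptide %s excluded: inactive (max signal %.3g <= %g)",
                    row.peptide_id, row.max_signal, min_signal)
    for row in activities[~inactive & nonlinear].itertuples(index=False):
        logger.info("peptide %s excluded: non-linear (R^2 %.3f < %g)",
                    row.peptide_id, row.r2, min_r2)
    return activities[~inactive & ~nonlinear].reset_index(drop=True)


def average_activities(activity_frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean per-peptide activity across replicate wells of one condition.

    Only peptides present (i.e. QC-passed) in every replicate are kept; slope
    and r2 are averaged, max_signal takes the maximum.
    """
    if not activity_frames:
        raise ValueError("no activity frames to average")
    common = set(activity_frames[0]["peptide_id"])
    for frame in activity_frames[1:]:
        common &= set(frame["peptide_id"])
    frames = [f[f["peptide_id"].isin(common)].set_index("peptide_id").sort_index()
              for f in activity_frames]
    stacked = pd.concat(frames, keys=range(len(frames)))
    out = stacked.groupby(level=1).agg(
        slope=("slope", "mean"), r2=("r2", "mean"), max_signal=("max_signal", "max"))
    return out.reset_index().rename(columns={"index": "peptide_id"})[ACTIVITY_COLUMNS]


def peptide_fold_changes(
    case: pd.DataFrame,
    control: pd.DataFrame,
    fc_hi: float = 1.15,
    fc_lo: float = 0.85,
) -> pd.DataFrame:
    """Case/control slope ratios and differential-phosphorylation calls.

    Only peptides present in both conditions are compared; a non-positive
    control slope makes the ratio meaningless and the peptide is skipped with
    a logged reason. Differential iff fc > fc_hi or fc < fc_lo (both strict:
    a fold change of exactly 1.15 is not called).
    """
    merged = case.merge(control, on="peptide_id", suffixes=("_case", "_ctrl"))
    bad = merged["slope_ctrl"] <= 0
    for row in merged[bad].itertuples(index=False):
        logger.info("peptide %s skipped: control slope %.3g <= 0",
                    row.peptide_id, row.slope_ctrl)
    merged = merged[~bad]
    fc = merged["slope_case"] / merged["slope_ctrl"]
    return pd.DataFrame({
        "peptide_id": merged["peptide_id"].to_numpy(),
        "fc": fc.to_numpy(),
        "log2fc": np.log2(fc.to_numpy()),
        "differential": ((fc > fc_hi) | (fc < fc_lo)).to_numpy(),
    })


def krsa_zscores(
    differential_peptides: Iterable[str],
    chip_peptides: Iterable[str],
    kinase_map: Mapping[str, Iterable[str]],
    n_iter: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-chip kinase enrichment z-scores by random sampling.

    For each kinase, the observed count of differential peptides among its
    on-chip mapped peptides is compared to the counts in ``n_iter`` uniform
    random draws (without replacement) of equally many peptides from the chip:
    z = (observed - null mean) / null sd. A null sd below the floor (e.g. a
    kinase mapping the whole chip) reports z = 0. Columns: kinase_id,
    observed, null_mean, null_sd, z, n_mapped_peptides.
    """
    chip = sorted(set(chip_peptides))
    diff = set(differential_peptides)
    if not diff:
        raise ValueError("no differential peptides; KRSA z-scores are undefined")
    if not diff <= set(chip):
        raise ValueError("differential peptides must be a subset of chip peptides")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")

    index = {p: i for i, p in enumerate(chip)}
    n_chip, n_diff = len(chip), len(diff)
    rng = np.random.default_rng(seed)
    # one uniform random subset of size n_diff per iteration, as an indicator
    keys = rng.random((n_iter, n_chip))
    cut = np.partition(keys, n_diff - 1, axis=1)[:, n_diff - 1:n_diff]
    indicator = keys <= cut  # n_iter x n_chip, exactly n_diff True per row

    rows = []
    for kinase_id in sorted(kinase_map):
        mapped = {p for p in kinase_map[kinase_id] if p in index}
        if not mapped:
            logger.info("kinase %s skipped: no mapped peptide on chip", kinase_id)
            continue
        cols = [index[p] for p in mapped]
        null_counts = indicator[:, cols].sum(axis=1)
        mu = float(null_counts.mean())
        sd = float(null_counts.std(ddof=0))
        observed = len(diff & mapped)
        z = 0.0 if sd < SD_FLOOR else (observed - mu) / sd
        rows.append({"kinase_id": kinase_id, "observed": observed,
                     "null_mean": mu, "null_sd": sd, "z": z,
                     "n_mapped_peptides": len(mapped)})
    return pd.DataFrame(rows, columns=["kinase_id", "observed", "null_mean",
                                       "null_sd", "z", "n_mapped_peptides"])


def average_zscores(per_chip: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-chip z-scores into final kinase scores.

    Kinases are kept if they were scored on at least one chip; z_per_chip
    lists the available per-chip values and z_mean is their mean.
    """
    if not per_chip:
        raise ValueError("no per-chip score tables")
    collected: dict[str, dict] = {}
    for frame in per_chip:
        for row in frame.itertuples(index=False):
            entry = collected.setdefault(
                row.kinase_id, {"z": [], "n_mapped": row.n_mapped_peptides})
            entry["z"].append(row.z)
    rows = [
        {"kinase_id": k, "z_per_chip": e["z"],
         "z_mean": float(np.mean(e["z"])), "n_mapped_peptides": e["n_mapped"]}
        for k, e in sorted(collected.items())
    ]
    table = pd.DataFrame(rows, columns=["kinase_id", "z_per_chip", "z_mean",
                                        "n_mapped_peptides"])
    return table.sort_values("z_mean", ascending=False, kind="stable").reset_index(drop=True)


def family_aggregate(
    peptide_log2fcs: pd.DataFrame,
    family_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Mean +/- SD of peptide log2 fold changes per kinase family.

    ``peptide_log2fcs`` is indexed by peptide ID with one column per
    comparison (e.g. noise vs control, drug vs control, noise+drug vs
    control). SD uses ddof=1; a single-peptide family reports SD = 0.
    """
    rows = []
    for family, peptides in sorted(family_map.items()):
        members = [p for p in peptides if p in peptide_log2fcs.index]
        if not members:
            logger.info("family %s skipped: no member peptide present", family)
            continue
        sub = peptide_log2fcs.loc[members]
        for comparison in peptide_log2fcs.columns:
            values = sub[comparison].to_numpy(dtype=float)
            sd = 0.0 if len(values) == 1 else float(np.std(values, ddof=1))
            rows.append({"family": family, "comparison": comparison,
                         "n_peptides": len(values),
                         "mean_log2fc": float(values.mean()), "sd_log2fc": sd})
    return pd.DataFrame(rows, columns=["family", "comparison", "n_peptides",
                                       "mean_log2fc", "sd_log2fc"])


def quartile_harmonize(rankings: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Harmonize kinase rankings from several methods onto a quartile scale.

    Within each method, the kinase at (1-based) rank r of n is assigned
    quartile ceil(4*r/n); quartile 1 is the top of the ranking. Kinases absent
    from a method are left as NaN. Requires at least two methods.
    """
    if len(rankings) < 2:
        raise ValueError("need rankings from >=2 methods to harmonize")
    columns = {}
    for method, ranking in rankings.items():
        ranking = list(ranking)
        if not ranking:
            raise ValueError(f"empty ranking for method {method!r}")
        n = len(ranking)
        columns[method] = {k: math.ceil(4 * (r + 1) / n)
                           for r, k in enumerate(ranking)}
    kinases = sorted({k for col in columns.values() for k in col})
    data = {m: [col.get(k, np.nan) for k in kinases] for m, col in columns.items()}
    return pd.DataFrame(data, index=pd.Index(kinases, name="kinase_id"))
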