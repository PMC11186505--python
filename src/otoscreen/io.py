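"""Readers and writers for the pipeline's file formats.

Formats: expression matrices and report tables as TSV; gene sets and
kinase-to-peptide maps as GMT; drug compendia and ground-truth sidecars as
JSON; chip runs as TSV with a commented metadata header; PK profiles as CSV.
All writers emit a commented header carrying the package version and, when
given, the configuration hash and seed, so two runs with identical effective
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .types import (
    ConcTimeProfile,
    DrugSignature,
    KinomeChipRun,
    SignatureCompendium,
    SyntheticTruth,
    normalize_gene,
)

logger = logging.getLogger(__name__)


def _metadata_lines(config: PipelineConfig = None, seed: int = None, **extra) -> list[str]:
    lines = [f"# otoscreen {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash()}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key, value in extra.items():
        lines.append(f"# {key}: {value}")
    return lines


# -- expression matrices ---------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Expression TSV/CSV: first column gene IDs, header row sample IDs.

    Duplicate gene rows are collapsed by mean (with a logged warning);
    duplicate sample IDs or non-numeric cells are errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    header = next((line for line in path.read_text().splitlines()
                   if line.strip() and not line.startswith("#")), "")
    samples = header.split(sep)[1:]
    if len(set(samples)) != len(samples):  # read_csv would mangle these
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample IDs {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from None
    df.index = [normalize_gene(g) for g in df.index]
    df.index.name = "gene"
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene row(s) collapsed by mean", path, n)
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_expression(matrix: pd.DataFrame, path, config=None, seed=None) -> None:
    write_table(matrix.reset_index(), path, config=config, seed=seed)


# -- generic tables --------------------------------------------------------

def write_table(table: pd.DataFrame, path, config=None, seed=None) -> None:
    """Tab-separated table with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_lines(config=config, seed=seed):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- gene sets (GMT) -------------------------------------------------------

def read_gmt(path) -> dict:
    """Standard GMT: name, description, then tab-separated member genes."""
    sets = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
        name = fields[0].strip()
        members = frozenset(normalize_gene(g) for g in fields[2:] if g.strip())
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets, path, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = sorted(sets[name])
            fh.write("\t".join([name, description or "na", *members]) + "\n")


# -- drug compendium (JSON) ------------------------------------------------

def read_compendium(path) -> SignatureCompendium:
    """Compendium JSON: {"drugs": [{"id", "up", "down", "vector"?}, ...]}.

    DrugSignature validation rejects overlapping up/down sets or vector signs
    that contradict set membership.
    """
    data = json.loads(Path(path).read_text())
    if "drugs" not in data or not isinstance(data["drugs"], list):
        raise ValueError(f"{path}: compendium JSON must have a 'drugs' list")
    sigs = []
    for i, entry in enumerate(data["drugs"]):
        for field in ("id", "up", "down"):
            if field not in entry:
                raise ValueError(f"{path}: drug #{i} missing field {field!r}")
        sigs.append(DrugSignature(drug_id=entry["id"],
                                  up=frozenset(entry["up"]),
                                  down=frozenset(entry["down"]),
                                  vector=entry.get("vector")))
    return SignatureCompendium(sigs)


def write_compendium(compendium: SignatureCompendium, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"drugs": [
        {"id": sig.drug_id, "up": sorted(sig.up), "down": sorted(sig.down),
         **({"vector": dict(sorted(sig.vector.items()))} if sig.vector else {})}
        for sig in compendium
    ]}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# -- chip runs (TSV) -------------------------------------------------------

def read_chip_run(path) -> KinomeChipRun:
    """Chip-run TSV: '# well_id:'/'# condition:' headers, then a peptide
    column and one numeric column per exposure time (ms); >=3 required."""
    path = Path(path)
    meta = {}
    for raw in path.read_text().splitlines():
        if raw.startswith("#") and ":" in raw:
            key, _, value = raw.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        elif not raw.startswith("#"):
            break
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        df.columns = [float(c) for c in df.columns]
    except ValueError:
        raise ValueError(f"{path}: exposure columns must be numeric (ms)") from None
    if len(df.columns) < 3:
        raise ValueError(f"{path}: chip run needs >=3 exposure columns")
    return KinomeChipRun(well_id=meta.get("well_id", path.stem),
                         condition=meta.get("condition", "unknown"),
                         intensities=df.astype(float))


def write_chip_run(run: KinomeChipRun, path, config=None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_lines(config=config, seed=seed,
                                    well_id=run.well_id, condition=run.condition):
            fh.write(line + "\n")
        out = run.intensities.copy()
        out.columns = [format(c, "g") for c in out.columns]
        out.to_csv(fh, sep="\t")


# -- PK profiles (CSV) -----------------------------------------------------

def read_pk(path) -> ConcTimeProfile:
    """PK CSV with 'time_h' and 'conc_ng_ml' columns; dose and LLOQ come from
    '# dose_mg_per_kg:' / '# lloq_ng_per_ml:' header comments."""
    path = Path(path)
    meta = {}
    for raw in path.read_text().splitlines():
        if raw.startswith("#") and ":" in raw:
            key, _, value = raw.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "conc_ng_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "dose_mg_per_kg" not in meta:
        raise ValueError(f"{path}: missing '# dose_mg_per_kg:' header")
    return ConcTimeProfile(times=df["time_h"].to_numpy(float),
                           concentrations=df["conc_ng_ml"].to_numpy(float),
                           dose=float(meta["dose_mg_per_kg"]),
                           lloq=float(meta.get("lloq_ng_per_ml", 5.0)))


def write_pk(profile: ConcTimeProfile, path, config=None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_lines(config=config, seed=seed,
                                    dose_mg_per_kg=profile.dose,
                                    lloq_ng_per_ml=profile.lloq):
            fh.write(line + "\n")
        pd.DataFrame({"time_h": profile.times,
                      "conc_ng_ml": profile.concentrations}).to_csv(fh, index=False)


# -- ground-truth sidecars (JSON) ------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "planted_up_genes": sorted(truth.planted_up_genes),
        "planted_down_genes": sorted(truth.planted_down_genes),
        "planted_reverser_drugs": sorted(truth.planted_reverser_drugs),
        "enriched_set_ids": sorted(truth.enriched_set_ids),
        "kinase_activity_map": dict(sorted(truth.kinase_activity_map.items())),
        "pk_params": truth.pk_params,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_up_genes=frozenset(data.get("planted_up_genes", [])),
        planted_down_genes=frozenset(data.get("planted_down_genes", [])),
        planted_reverser_drugs=frozenset(data.get("planted_reverser_drugs", [])),
        enriched_set_ids=frozenset(data.get("enriched_set_ids", [])),
        kinase_activity_map=data.get("kinase_activity_map", {}),
        pk_params=data.get("pk_params", {}),
    )
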