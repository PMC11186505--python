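"""Core value types shared across pipeline stages.

Gene identifiers are normalized (whitespace-trimmed, upper-cased) at type
boundaries so that mouse-style symbols ("Egfr") and upper-case symbols
("EGFR") compare equal everywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd


def normalize_gene(gene: str) -> str:
    """Canonical form of a gene identifier: trimmed and upper-cased."""
    return str(gene).strip().upper()


def normalize_drug(drug: str) -> str:
    """Canonical form of a drug/perturbation name: trimmed, case-folded."""
    return str(drug).strip().casefold()


@dataclass(frozen=True)
class SignedGeneSet:
    """A directional gene signature: disjoint up- and down-regulated sets."""

    up: frozenset
    down: frozenset

    def __post_init__(self):
        up = frozenset(normalize_gene(g) for g in self.up)
        down = frozenset(normalize_gene(g) for g in self.down)
        if up & down:
            raise ValueError(
                f"up and down sets must be disjoint; shared: {sorted(up & down)[:5]}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def genes(self) -> frozenset:
        return self.up | self.down


@dataclass(frozen=True)
class DrugSignature:
    """A drug perturbation signature: up/down gene sets, optional signed vector.

    The optional ``vector`` maps gene -> signed characteristic value; its sign
    must agree with set membership for genes that appear in ``up`` or ``down``.
    """

    drug_id: str
    up: frozenset
    down: frozenset
    vector: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "drug_id", normalize_drug(self.drug_id))
        up = frozenset(normalize_gene(g) for g in self.up)
        down = frozenset(normalize_gene(g) for g in self.down)
        if up & down:
            raise ValueError(
                f"drug {self.drug_id!r}: up and down sets intersect: "
                f"{sorted(up & down)[:5]}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if self.vector is not None:
            vec = {normalize_gene(g): float(v) for g, v in self.vector.items()}
            for g in up:
                if g in vec and vec[g] <= 0:
                    raise ValueError(f"drug {self.drug_id!r}: vector sign of {g} "
                                     "contradicts up-set membership")
            for g in down:
                if g in vec and vec[g] >= 0:
                    raise ValueError(f"drug {self.drug_id!r}: vector sign of {g} "
                                     "contradicts down-set membership")
            object.__setattr__(self, "vector", vec)


class SignatureCompendium:
    """An ordered collection of named drug signatures."""

    def __init__(self, signatures):
        sigs = list(signatures)
        ids = [s.drug_id for s in sigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate drug_id in compendium")
        self._sigs = {s.drug_id: s for s in sigs}

    def __len__(self):
        return len(self._sigs)

    def __iter__(self):
        return iter(self._sigs.values())

    def __contains__(self, drug_id):
        return normalize_drug(drug_id) in self._sigs

    def __getitem__(self, drug_id) -> DrugSignature:
        return self._sigs[normalize_drug(drug_id)]

    @property
    def drug_ids(self):
        return list(self._sigs)


@dataclass(frozen=True)
class KinomeChipRun:
    """One well of a kinase peptide array: peptide x exposure-time intensities.

    ``intensities`` is a DataFrame indexed by peptide ID whose columns are
    exposure times in milliseconds (strictly increasing, at least three).
    """

    well_id: str
    condition: str
    intensities: pd.DataFrame

    def __post_init__(self):
        cols = np.asarray(self.intensities.columns, dtype=float)
        if len(cols) < 3:
            raise ValueError("chip run needs >=3 exposure points")
        if not np.all(np.diff(cols) > 0):
            raise ValueError("exposure times must be strictly increasing")
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise ValueError("non-finite intensity values")

    @property
    def exposures(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    @property
    def peptides(self):
        return list(self.intensities.index)


@dataclass(frozen=True)
class ConcTimeProfile:
    """A concentration-time profile with its dose and assay LLOQ.

    Concentrations in ng/ml, times in hours, dose in mg/kg. ``quantifiable``
    marks points at or above the LLOQ; ``lloq_censor`` in the NCA stage uses
    and updates it.
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    lloq: float = 5.0
    quantifiable: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise ValueError("times and concentrations must be equal-length 1-D")
        if len(t) and t[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        q = self.quantifiable
        q = c >= self.lloq if q is None else np.asarray(q, dtype=bool)
        if len(q) != len(t):
            raise ValueError("quantifiable mask length mismatch")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "quantifiable", q)

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class NcaResult:
    """Non-compartmental PK parameters derived from one profile."""

    cmax: float          # ng/ml
    tmax: float          # h
    auc_0t: float        # ng/ml*h
    auc_inf: float       # ng/ml*h
    lambda_z: float      # 1/h
    t_half: float        # h
    cl_f: float          # (mg/kg)/(ng/ml)/h
    vz_f: float          # (mg/kg)/(ng/ml)
    n_lambda_points: int = 0
    lambda_r2_adj: float = float("nan")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic-data generators.

    Consuming-stage tests compare recovered signals against these fields.
    """

    planted_up_genes: frozenset = frozenset()
    planted_down_genes: frozenset = frozenset()
    planted_reverser_drugs: frozenset = frozenset()
    enriched_set_ids: frozenset = frozenset()
    kinase_activity_map: dict = field(default_factory=dict)
    pk_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.planted_up_genes = frozenset(normalize_gene(g) for g in self.planted_up_genes)
        self.planted_down_genes = frozenset(normalize_gene(g) for g in self.planted_down_genes)
        if self.planted_up_genes & self.planted_down_genes:
            raise ValueError("planted up and down gene sets must be disjoint")
        self.planted_reverser_drugs = frozenset(
            normalize_drug(d) for d in self.planted_reverser_drugs
        )
        self.enriched_set_ids = frozenset(self.enriched_set_ids)
        for k, mult in self.kinase_activity_map.items():
            if mult <= 0:
                raise ValueError(f"kinase activity multiplier for {k} must be > 0")
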