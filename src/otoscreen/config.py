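"""Pipeline configuration.

Defaults are the published thresholds of the screening procedure this package
reimplements: DEGs called at |logFC| > 2 with P < 0.05 on the array path, or
linear |FC| > 1.2 with FDR q < 0.05 on the single-cell path; connectivity
queries require at least 3 up- and 3 down-regulated member DEGs, return the
top 50 perturbations, and keep hits with overlap score > 0.1; pathways with
at least 3 hits are retained; kinome peptides must exceed raw signal 5 with a
kinetic-fit R^2 of at least 0.90, and fold changes outside (0.85, 1.15) are
called differential.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class DegThresholds:
    logfc_cut: float = 2.0        # log2 units, array regime
    p_cut: float = 0.05
    use_q: bool = False
    q_cut: float = 0.05           # single-cell regime
    fc_cut_linear: float = 1.2    # linear ratio, single-cell regime

    def __post_init__(self):
        if not (0 < self.p_cut <= 1) or not (0 < self.q_cut <= 1):
            raise ValueError("p_cut and q_cut must lie in (0, 1]")
        if self.logfc_cut < 0 or self.fc_cut_linear <= 0:
            raise ValueError("fold-change cutoffs must be non-negative")


@dataclass
class QueryRules:
    min_up: int = 3
    min_down: int = 3
    top_k: int = 50
    score_cutoff: float = 0.1

    def __post_init__(self):
        if self.min_up < 1 or self.min_down < 1:
            raise ValueError("min_up and min_down must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class ConsensusRules:
    min_pathway_hits: int = 3
    min_pathways_per_drug: int = 2


@dataclass
class KinomeSettings:
    min_signal: float = 5.0
    min_r2: float = 0.90
    fc_hi: float = 1.15
    fc_lo: float = 0.85
    n_iter: int = 2000

    def __post_init__(self):
        if not (self.fc_lo < 1 < self.fc_hi):
            raise ValueError("fold-change gates must straddle 1 (fc_lo < 1 < fc_hi)")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")


@dataclass
class PipelineConfig:
    deg: DegThresholds = field(default_factory=DegThresholds)
    query: QueryRules = field(default_factory=QueryRules)
    consensus: ConsensusRules = field(default_factory=ConsensusRules)
    kinome: KinomeSettings = field(default_factory=KinomeSettings)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        return cls(
            deg=DegThresholds(**d.get("deg", {})),
            query=QueryRules(**d.get("query", {})),
            consensus=ConsensusRules(**d.get("consensus", {})),
            kinome=KinomeSettings(**d.get("kinome", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat YAML (or JSON, a YAML subset) mapping."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short digest of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
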