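"""Synthetic-data generators with planted ground truth.

Every input the screening pipeline consumes can be generated here with a known
answer: two-group expression matrices with planted differential genes, a drug
signature compendium with planted "reverser" drugs, gene-set collections with
planted enriched sets, kinase-array kinetic reads with planted kinase-family
activity shifts, and one-compartment oral-absorption concentration profiles.
All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ConcTimeProfile,
    DrugSignature,
    KinomeChipRun,
    SignatureCompendium,
    SignedGeneSet,
    SyntheticTruth,
    normalize_gene,
)

# Perilymph-like defaults: oral 15 mg/kg with Tmax ~0.5 h, t1/2 ~2.1 h and
# Cmax ~100 ng/ml on the noiseless curve.
DEFAULT_PK_PARAMS = {"ka": 6.2, "ke": 0.33, "V_over_F": 127.0, "dose": 15.0}
DEFAULT_PK_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)  # h, sparse sampling design


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def gen_expression(
    n_genes: int = 2000,
    n_per_group: int = 5,
    n_up: int = 20,
    n_down: int = 20,
    effect_log2fc: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 8.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Two-group log2 expression matrix with planted differential genes.

    Treated-group means of the first ``n_up`` genes are shifted by
    ``+effect_log2fc`` and the next ``n_down`` by ``-effect_log2fc``; all other
    genes have zero true log-fold-change. I.i.d. Gaussian noise of standard
    deviation ``noise_sd`` (log2 units) is added to every cell. Columns are
    named ``case_*`` / ``control_*`` so the design can be read off the header.
    """
    if n_genes <= 0 or n_per_group < 3:
        raise ValueError("need n_genes > 0 and n_per_group >= 3")
    if n_up < 0 or n_down < 0 or n_up + n_down >= n_genes:
        raise ValueError("need 0 <= n_up + n_down < n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be >= 0")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = [f"case_{i}" for i in range(1, n_per_group + 1)] + [
        f"control_{i}" for i in range(1, n_per_group + 1)
    ]
    mean = np.full((n_genes, 2 * n_per_group), baseline)
    mean[:n_up, :n_per_group] += effect_log2fc
    mean[n_up:n_up + n_down, :n_per_group] -= effect_log2fc
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    truth = SyntheticTruth(
        planted_up_genes=frozenset(genes[:n_up]),
        planted_down_genes=frozenset(genes[n_up:n_up + n_down]),
    )
    return matrix, truth


def design_from_columns(matrix: pd.DataFrame) -> dict:
    """Recover the sample -> group mapping from ``case_*``/``control_*`` names."""
    design = {}
    for col in matrix.columns:
        group = col.rsplit("_", 1)[0]
        design[col] = group
    return design


def gen_compendium(
    n_drugs: int = 200,
    sig_size: int = 30,
    universe: Sequence[str] = (),
    query: SignedGeneSet = None,
    n_reversers: int = 5,
    concordance: float = 0.8,
    background_concordance: float = 0.1,
    seed: int = 0,
) -> tuple[SignatureCompendium, SyntheticTruth]:
    """Drug-signature compendium with planted reverser drugs.

    A reverser places each query up-gene in its down set (and vice versa) with
    probability ``concordance``; background drugs do so at
    ``background_concordance``. Signature sets are padded to ``sig_size`` genes
    per side with genes outside the query, so padding never changes a score.
    """
    if query is None or len(query) == 0:
        raise ValueError("query must be a non-empty SignedGeneSet")
    if not (0 <= background_concordance < concordance <= 1):
        raise ValueError("need 0 <= background_concordance < concordance <= 1")
    if n_reversers > n_drugs:
        raise ValueError("n_reversers cannot exceed n_drugs")
    universe = [normalize_gene(g) for g in universe]
    fillers = sorted(set(universe) - set(query.genes))
    if len(fillers) < sig_size:
        raise ValueError("universe too small for requested sig_size after "
                         "removing query genes")

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_drugs)))
    sigs = []
    reversers = []
    q_up = sorted(query.up)
    q_down = sorted(query.down)
    for i in range(n_drugs):
        drug_id = f"drug_{i + 1:0{width}d}"
        planted = i < n_reversers
        rate = concordance if planted else background_concordance
        if planted:
            reversers.append(drug_id)
        # reverse-mode concordance: query up genes land in the drug's down set
        down = {g for g in q_up if rng.random() < rate}
        up = {g for g in q_down if rng.random() < rate}
        n_pad_up = max(0, sig_size - len(up))
        n_pad_down = max(0, sig_size - len(down))
        pad = rng.choice(len(fillers), size=n_pad_up + n_pad_down, replace=False)
        up |= {fillers[j] for j in pad[:n_pad_up]}
        down |= {fillers[j] for j in pad[n_pad_up:]}
        sigs.append(DrugSignature(drug_id=drug_id, up=frozenset(up), down=frozenset(down)))
    truth = SyntheticTruth(planted_reverser_drugs=frozenset(reversers))
    return SignatureCompendium(sigs), truth


def gen_genesets(
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (15, 30),
    universe: Sequence[str] = (),
    planted: SyntheticTruth = None,
    n_enriched: int = 5,
    seed: int = 0,
) -> dict:
    """Gene-set collection in which ``n_enriched`` sets are planted enriched.

    Each enriched set receives at least three planted up- and three planted
    down-regulated genes (so it passes the 3-up/3-down query eligibility rule)
    and is padded with non-planted genes; the remaining sets draw uniformly
    from the whole universe.
    """
    if planted is None:
        planted = SyntheticTruth()
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    lo, hi = set_size_range
    if lo < 6 or hi < lo:
        raise ValueError("set sizes must allow 3 up + 3 down members (lo >= 6)")
    universe = [normalize_gene(g) for g in universe]
    if len(set(universe)) < hi:
        raise ValueError("universe too small for requested set sizes")
    up_pool = sorted(planted.planted_up_genes)
    down_pool = sorted(planted.planted_down_genes)
    if n_enriched > 0 and (len(up_pool) < 3 or len(down_pool) < 3):
        raise ValueError("need >=3 planted genes per direction to plant enrichment")
    neutral = sorted(set(universe) - set(up_pool) - set(down_pool))

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_sets)))
    sets = {}
    for i in range(n_sets):
        set_id = f"SET_{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            members = set(rng.choice(up_pool, size=3, replace=False))
            members |= set(rng.choice(down_pool, size=3, replace=False))
            n_pad = max(0, size - len(members))
            members |= {neutral[j] for j in rng.choice(len(neutral), size=n_pad,
                                                       replace=False)}
        else:
            members = {universe[j] for j in rng.choice(len(universe), size=size,
                                                       replace=False)}
        sets[set_id] = frozenset(members)
    return sets


def gen_kinome_run(
    peptide_map: Mapping[str, Iterable[str]],
    exposures: Sequence[float] = (5.0, 25.0, 100.0),
    base_slope: float = 2.0,
    activity: Mapping[str, float] = None,
    noise_sd: float = 0.0,
    n_wells: int = 3,
    seed: int = 0,
    condition: str = "case",
) -> list[KinomeChipRun]:
    """Kinetic peptide-array wells with planted kinase activity multipliers.

    Intensity of a peptide at exposure ``e`` is ``base_slope * m * e`` plus
    Gaussian noise, where ``m`` is the largest activity multiplier among the
    kinases mapping to that peptide (1.0 for unmapped kinases or when
    ``activity`` is empty, i.e. a control condition).
    """
    if not peptide_map:
        raise ValueError("peptide_map must not be empty")
    if len(exposures) < 3:
        raise ValueError("need >=3 exposure points")
    if base_slope <= 0:
        raise ValueError("base_slope must be > 0")
    activity = dict(activity or {})
    peptides = sorted({p for pep_set in peptide_map.values() for p in pep_set})
    index = {p: i for i, p in enumerate(peptides)}
    # multi-kinase peptides take the maximum multiplier across their kinases
    mult = np.ones(len(peptides))
    for kinase, pep_set in peptide_map.items():
        m = activity.get(kinase, 1.0)
        for p in pep_set:
            mult[index[p]] = max(mult[index[p]], m)

    rng = np.random.default_rng(seed)
    exposures = np.asarray(exposures, dtype=float)
    runs = []
    for w in range(1, n_wells + 1):
        clean = base_slope * np.outer(mult, exposures)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
        df = pd.DataFrame(noisy, index=pd.Index(peptides, name="peptide"),
                          columns=exposures)
        runs.append(KinomeChipRun(well_id=f"{condition}_well_{w}",
                                  condition=condition, intensities=df))
    return runs


def pk_concentration(params: Mapping[str, float], times) -> np.ndarray:
    """Noise-free one-compartment oral-absorption curve.

    C(t) = dose*ka / (V_over_F*(ka-ke)) * (exp(-ke*t) - exp(-ka*t)), the
    Bateman function. With dose in mg/kg and V_over_F in L/kg, dose/V_over_F
    is mg/L; the returned concentrations are scaled to ng/ml.
    """
    ka, ke = float(params["ka"]), float(params["ke"])
    if ka == ke:
        raise ValueError("ka == ke makes the closed form degenerate")
    dose, vf = float(params["dose"]), float(params["V_over_F"])
    t = np.asarray(times, dtype=float)
    scale = dose * ka / (vf * (ka - ke)) * 1000.0  # mg/L -> ng/ml
    return scale * (np.exp(-ke * t) - np.exp(-ka * t))


def pk_tmax(params: Mapping[str, float]) -> float:
    """Closed-form time of maximum concentration, ln(ka/ke)/(ka-ke)."""
    ka, ke = float(params["ka"]), float(params["ke"])
    if ka == ke:
        raise ValueError("ka == ke makes the closed form degenerate")
    return math.log(ka / ke) / (ka - ke)


def gen_pk_profile(
    params: Mapping[str, float] = None,
    times: Sequence[float] = DEFAULT_PK_TIMES,
    noise_cv: float = 0.0,
    seed: int = 0,
    lloq: float = 5.0,
) -> tuple[ConcTimeProfile, SyntheticTruth]:
    """Sampled concentration profile with multiplicative lognormal noise.

    ``noise_cv`` is the coefficient of variation of the unit-mean lognormal
    noise factor; concentrations stay positive by construction.
    """
    params = dict(DEFAULT_PK_PARAMS if params is None else params)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0) or (len(t) and t[0] < 0):
        raise ValueError("times must be sorted, non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    conc = pk_concentration(params, t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        factor = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=len(t))
        conc = conc * factor
    profile = ConcTimeProfile(times=t, concentrations=conc,
                              dose=params["dose"], lloq=lloq)
    return profile, SyntheticTruth(pk_params=params)
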