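"""Connectivity screening: scoring drug signatures against signed queries.

A query (up/down DEG sets) is compared to every drug signature in a
compendium in "mimic" or "reverse" mode. The overlap score is the fraction of
query genes whose direction is concordant (mimic) or anticoncordant (reverse)
with the signature, bounded in [0, 1]; the denominator is the full query size,
so genes absent from a signature count as discordant and scores are comparable
across drugs. For signatures that carry a signed characteristic vector, a
cosine-similarity score over the shared gene space is available as well.
"""

from __future__ import annotations

import math

import pandas as pd

from .types import DrugSignature, SignatureCompendium, SignedGeneSet

RESULT_COLUMNS = ["query_id", "drug_id", "mode", "score", "scoring", "rank"]

MODES = ("mimic", "reverse")


def overlap_score(query: SignedGeneSet, sig: DrugSignature, mode: str = "reverse") -> float:
    """Fraction of query genes mimicked (or reversed) by the signature."""
    if len(query) == 0:
        raise ValueError("overlap score undefined for an empty query")
    if mode == "mimic":
        concordant = len(query.up & sig.up) + len(query.down & sig.down)
    elif mode == "reverse":
        concordant = len(query.up & sig.down) + len(query.down & sig.up)
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return concordant / len(query)


def cosine_score(query: SignedGeneSet, sig: DrugSignature) -> float:
    """Cosine similarity between the query's +/-1 encoding and the signature
    vector, over genes present in both gene spaces.

    Ranking by descending similarity is equivalent to ascending cosine
    distance 1 - cos. Raises if either restricted vector has zero norm.
    """
    if sig.vector is None:
        raise ValueError(f"drug {sig.drug_id!r} has no signature vector")
    shared = (query.up | query.down) & set(sig.vector)
    dot = 0.0
    q_norm2 = 0.0
    s_norm2 = 0.0
    for g in shared:
        qv = 1.0 if g in query.up else -1.0
        sv = sig.vector[g]
        dot += qv * sv
        q_norm2 += qv * qv
        s_norm2 += sv * sv
    if q_norm2 == 0.0 or s_norm2 == 0.0:
        raise ValueError("zero-norm vector in cosine score (no shared genes?)")
    return dot / math.sqrt(q_norm2 * s_norm2)


def query_compendium(
    query: tuple[str, SignedGeneSet],
    compendium: SignatureCompendium,
    mode: str = "reverse",
    scoring: str = "overlap",
    top_k: int = 50,
) -> pd.DataFrame:
    """Score all drugs against one query and return the ranked top K.

    Results are sorted by score descending with drug ID as the deterministic
    tie-break, then truncated to ``min(top_k, n_drugs)`` with ranks 1..K.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(compendium) == 0:
        raise ValueError("empty compendium")
    query_id, signed = query
    if scoring == "overlap":
        scores = [(sig.drug_id, overlap_score(signed, sig, mode)) for sig in compendium]
    elif scoring == "cosine":
        sims = [(sig.drug_id, cosine_score(signed, sig)) for sig in compendium]
        # reverse mode seeks anticorrelated signatures: rank by -cos
        scores = [(d, -s) for d, s in sims] if mode == "reverse" else sims
    else:
        raise ValueError(f"scoring must be 'overlap' or 'cosine', got {scoring!r}")
    scores.sort(key=lambda item: (-item[1], item[0]))
    top = scores[: min(top_k, len(scores))]
    return pd.DataFrame({
        "query_id": query_id,
        "drug_id": [d for d, _ in top],
        "mode": mode,
        "score": [s for _, s in top],
        "scoring": scoring,
        "rank": range(1, len(top) + 1),
    })[RESULT_COLUMNS]


def filter_by_score(results: pd.DataFrame, cutoff: float = 0.1) -> pd.DataFrame:
    """Keep results with score strictly greater than the cutoff.

    A score exactly equal to the cutoff is removed (the published rule is
    "overlap score > 0.1"). Pre-filter ranks are preserved.
    """
    return results[results["score"] > cutoff].reset_index(drop=True)
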