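"""Map a candidate gene list onto a built network and rank it.

A noisy candidate list (for instance the genes inside copy-number
variants of uncertain significance) is intersected with the network's
node set, ranked by the betweenness already computed on the full
network — never recomputed on the mapped subgraph, so that relative
centralities stay comparable to the full network's maximum — and cut
into top-fraction sublists for downstream over-representation analysis.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord
from .network_builder import PPINetwork
from .topology import rank_by_betweenness

logger = logging.getLogger(__name__)

__all__ = [
    "map_candidates",
    "quantile_sublists",
    "classify_tpm",
    "annotate_expression",
    "seed_fraction",
]

#: TPM class boundaries: below 10 is "low", 10–50 inclusive is "medium",
#: above 50 is "high".
TPM_LOW_BELOW = 10.0
TPM_HIGH_ABOVE = 50.0


def map_candidates(
    net: PPINetwork,
    table: pd.DataFrame,
    candidates: Sequence[GeneRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Intersect candidates with the network and rank by betweenness.

    *table* is the centrality table computed on *net* (it may already
    carry a ``relative_betweenness`` column, which is preserved).  Seed
    annotations come from the candidate records where present, falling
    back to the network's node tags.  Candidates absent from the network
    (pseudogenes, non-coding entries, ...) are returned separately as the
    sorted *unmapped* list.

    Returns ``(prioritized, unmapped)`` where *prioritized* has columns
    ``symbol, betweenness[, relative_betweenness], seed_score, syndromic,
    rank`` sorted by decreasing betweenness.
    """
    # dedupe candidates, keeping first occurrence
    seen: set[str] = set()
    unique: list[GeneRecord] = []
    for rec in candidates:
        if rec.symbol not in seen:
            seen.add(rec.symbol)
            unique.append(rec)

    nodes = net.node_set
    mapped = [rec for rec in unique if rec.symbol in nodes]
    unmapped = sorted(rec.symbol for rec in unique if rec.symbol not in nodes)
    if not mapped:
        raise ValueError("no candidate gene maps onto the network")

    centrality = table.set_index("symbol")
    missing = [rec.symbol for rec in mapped if rec.symbol not in centrality.index]
    if missing:
        raise ValueError(
            f"centrality table does not cover mapped candidates, e.g. {missing[:5]}"
        )

    rows = []
    for rec in mapped:
        tags = net.node_tags.get(rec.symbol, {})
        score = rec.seed_score if rec.seed_score is not None else tags.get("seed_score")
        synd = rec.syndromic if rec.syndromic is not None else tags.get("syndromic")
        row = {
            "symbol": rec.symbol,
            "betweenness": float(centrality.at[rec.symbol, "betweenness"]),
            "seed_score": score,
            "syndromic": synd,
        }
        if "relative_betweenness" in centrality.columns:
            row["relative_betweenness"] = float(
                centrality.at[rec.symbol, "relative_betweenness"]
            )
        rows.append(row)
    prioritized = rank_by_betweenness(pd.DataFrame(rows))
    logger.info(
        "mapped %d/%d candidates onto the network (%d unmapped)",
        len(mapped),
        len(unique),
        len(unmapped),
    )
    return prioritized, unmapped


def quantile_sublists(
    prioritized: pd.DataFrame, fractions: Iterable[float]
) -> dict[float, list[str]]:
    """Cut the ranked list into top-fraction sublists.

    For fraction p the sublist is the first ``floor(p * n)`` genes of the
    ranked list (ties were already resolved by the ranking rule), so the
    sublists are nested.  A fraction whose cut would be empty is an error.
    """
    symbols = list(prioritized["symbol"])
    n = len(symbols)
    out: dict[float, list[str]] = {}
    for p in fractions:
        p = float(p)
        if not 0 < p <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {p}")
        # tiny epsilon guards against 0.2*455 = 90.999... style float error
        k = int(math.floor(p * n + 1e-9))
        if k == 0:
            raise ValueError(f"fraction {p} of {n} genes cuts an empty sublist")
        out[p] = symbols[:k]
    return out


def classify_tpm(tpm: float) -> str:
    """Classify a TPM value as ``low`` (<10), ``medium`` (10–50) or ``high`` (>50)."""
    tpm = float(tpm)
    if not np.isfinite(tpm) or tpm < 0:
        raise ValueError(f"TPM must be a non-negative number, got {tpm}")
    if tpm < TPM_LOW_BELOW:
        return "low"
    if tpm <= TPM_HIGH_ABOVE:
        return "medium"
    return "high"


def annotate_expression(
    prioritized: pd.DataFrame, tpm: Mapping[str, float]
) -> pd.DataFrame:
    """Attach per-gene TPM values and their low/medium/high class.

    Genes absent from *tpm* get NaN expression and no class.
    """
    out = prioritized.copy()
    values = [tpm.get(s, np.nan) for s in out["symbol"]]
    out["expression_tpm"] = values
    out["expression_class"] = [
        classify_tpm(v) if np.isfinite(v) else None for v in values
    ]
    return out


def seed_fraction(prioritized: pd.DataFrame, top_k: int) -> int:
    """Percent of the top-k ranked genes carrying any seed annotation.

    A gene counts if its ``seed_score`` is present or its ``syndromic``
    flag is true.  Reported as percent rounded to the nearest integer.
    """
    top_k = int(top_k)
    if top_k < 1 or top_k > len(prioritized):
        raise ValueError(f"top_k must be in [1, {len(prioritized)}], got {top_k}")
    top = prioritized.head(top_k)
    n_annotated = sum(
        1
        for _, row in top.iterrows()
        if pd.notna(row.get("seed_score")) or bool(row.get("syndromic"))
    )
    return int(round(100.0 * n_annotated / top_k))
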