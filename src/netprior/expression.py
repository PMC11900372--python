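"""Co-expression of top-ranked genes with a reference gene set.

Expression profiles (TPM across brain regions) of the top-ranked network
genes are correlated with the profiles of a reference set (for example
the high-confidence seed genes present in the network).  The default
transform is log2(TPM+1) because TPM spans several orders of magnitude;
raw-TPM mode is available.  Pearson correlation is the default method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "expression_correlation", "summarize_coexpression"]

TRANSFORMS = ("log2p1", "none")


@dataclass
class CorrelationMatrix:
    """Reference genes (rows) × top genes (columns) correlation matrix."""

    values: pd.DataFrame
    method: str
    dropped_reference: list[str] = field(default_factory=list)
    dropped_top: list[str] = field(default_factory=list)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise z-scores (ddof=1); constant rows become all-NaN."""
    centered = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / sd
    z[np.repeat(sd == 0, x.shape[1], axis=1)] = np.nan
    return z


def expression_correlation(
    expr: ExpressionMatrix,
    top_genes: Sequence[str],
    reference_genes: Sequence[str],
    transform: str = "log2p1",
) -> CorrelationMatrix:
    """Pearson correlation of each (reference, top) gene pair across regions.

    Genes missing from the expression matrix are dropped and reported.
    A gene with zero variance across regions yields NaN correlations
    rather than an error.  Requires at least two regions.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}, got {transform!r}")
    if len(expr.regions) < 2:
        raise ValueError("need at least two regions to correlate expression profiles")

    index = set(expr.values.index)
    top = [normalize_symbol(g) for g in dict.fromkeys(top_genes)]
    ref = [normalize_symbol(g) for g in dict.fromkeys(reference_genes)]
    top_present = [g for g in top if g in index]
    ref_present = [g for g in ref if g in index]
    dropped_top = [g for g in top if g not in index]
    dropped_ref = [g for g in ref if g not in index]
    if dropped_top or dropped_ref:
        logger.warning(
            "dropped %d top / %d reference gene(s) absent from the expression matrix",
            len(dropped_top),
            len(dropped_ref),
        )
    if not top_present or not ref_present:
        raise ValueError("no overlapping genes between expression matrix and gene lists")

    raw_top = expr.values.loc[top_present].to_numpy(dtype=float)
    raw_ref = expr.values.loc[ref_present].to_numpy(dtype=float)
    if transform == "log2p1":
        raw_top = np.log2(raw_top + 1.0)
        raw_ref = np.log2(raw_ref + 1.0)

    m = raw_top.shape[1]
    z_top = _standardize_rows(raw_top)
    z_ref = _standardize_rows(raw_ref)
    corr = (z_ref @ z_top.T) / (m - 1)
    corr = np.clip(corr, -1.0, 1.0)

    frame = pd.DataFrame(corr, index=ref_present, columns=top_present)
    method = f"pearson ({transform})"
    return CorrelationMatrix(
        values=frame,
        method=method,
        dropped_reference=dropped_ref,
        dropped_top=dropped_top,
    )


def summarize_coexpression(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Median correlation of each top gene with the reference set, ranked.

    NaN entries (zero-variance genes) are excluded from each median; a
    column with no finite value is reported with a NaN median and flagged
    in ``all_missing``.  Sorted descending by median (NaN last), with a
    1-based rank.
    """
    if matrix.values.empty:
        raise ValueError("empty correlation matrix")
    medians = matrix.values.median(axis=0, skipna=True)
    out = pd.DataFrame(
        {
            "symbol": medians.index,
            "median_correlation": medians.to_numpy(),
            "all_missing": matrix.values.isna().all(axis=0).to_numpy(),
        }
    )
    out = out.sort_values(
        ["median_correlation", "symbol"],
        ascending=[False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def coexpression_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Save a correlation heatmap (requires matplotlib, the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * matrix.values.shape[1]), max(4, 0.12 * matrix.values.shape[0]))
    )
    im = ax.imshow(matrix.values.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(matrix.values.shape[1]))
    ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.values.shape[0]))
    ax.set_yticklabels(matrix.values.index, fontsize=5)
    ax.set_title(matrix.method)
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
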