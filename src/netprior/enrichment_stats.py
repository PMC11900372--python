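"""Resampling validation and over-representation analysis (ORA).

Three statistical procedures live here:

* **Monte-Carlo seed-enrichment validation** — is the network's coverage
  of a seed category higher than that of equally sized random gene
  draws?  The null is built by repeatedly sampling ``|network|`` genes
  without replacement from the declared universe; the observed coverage
  is compared to the null by a two-sided one-sample t-test, with an
  empirical percentile reported alongside because the t approximation is
  aggressive at extreme observations.

* **ORA core** — one-sided Fisher exact test (hypergeometric upper tail)
  of the overlap between a query list and each pathway against a
  reference universe, with Benjamini–Hochberg FDR across pathways and
  the enrichment ratio ER = (k/n) / (K/N).

* **Random-ORA bias control** — size-matched random sublists of the
  mapped genes are run through ORA in triplicate; a pathway significant
  in at least two of three replicates is flagged as a dataset bias
  rather than a centrality-driven signal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PathwaySet, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "MonteCarloResult",
    "ORAResult",
    "monte_carlo_enrichment",
    "ora",
    "bh_fdr",
    "random_ora_control",
    "flag_biased",
    "apply_bias_flags",
]

FDR_THRESHOLD = 0.05


@dataclass
class MonteCarloResult:
    """Outcome of the Monte-Carlo seed-enrichment validation."""

    observed_pct: float  # percent of the category present in the network
    null_mean: float  # mean category coverage (percent) over random draws
    null_sd: float
    n_draws: int
    p_value: float  # two-sided one-sample t-test of null draws vs observed
    empirical_percentile: float  # (1 + #draws >= observed) / (n_draws + 1)
    t_statistic: float
    sample_size: int  # genes drawn per replicate (= network size)
    rng_seed: int


@dataclass
class ORAResult:
    """Per-pathway over-representation result."""

    pathway: str
    overlap_genes: frozenset[str]
    k: int  # overlap size
    n_list: int  # query size (within reference)
    K: int  # pathway size within reference
    N_ref: int  # reference universe size
    p_value: float
    fdr: float
    enrichment_ratio: float  # (k/n_list) / (K/N_ref)
    bias_flag: bool = False


def monte_carlo_enrichment(
    universe: Sequence[str],
    network_nodes: Iterable[str],
    category: Iterable[str],
    n_draws: int = 1000,
    rng_seed: int = 0,
) -> MonteCarloResult:
    """Monte-Carlo test of a seed category's coverage by the network.

    ``observed_pct`` is the percent of *category* genes found among
    *network_nodes*.  The null distribution draws ``|network_nodes|``
    genes without replacement from *universe* ``n_draws`` times and
    records the percent of the category covered by each draw.
    """
    universe_list = list(dict.fromkeys(normalize_symbol(g) for g in universe))
    nodes = {normalize_symbol(g) for g in network_nodes}
    cat = {normalize_symbol(g) for g in category}
    if not cat:
        raise ValueError("category must be non-empty")
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    sample_size = len(nodes)
    if sample_size > len(universe_list):
        raise ValueError(
            f"sample size {sample_size} exceeds universe size {len(universe_list)}"
        )

    observed = 100.0 * len(cat & nodes) / len(cat)

    rng = np.random.default_rng(rng_seed)
    in_category = np.fromiter(
        (g in cat for g in universe_list), dtype=bool, count=len(universe_list)
    )
    null = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(universe_list), size=sample_size, replace=False)
        null[i] = 100.0 * in_category[idx].sum() / len(cat)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        # degenerate null (every draw identical); t-test undefined
        t_stat = 0.0 if observed == null_mean else np.inf
        p_value = 1.0 if observed == null_mean else 0.0
    else:
        t_res = stats.ttest_1samp(null, popmean=observed)
        t_stat = float(t_res.statistic)
        p_value = float(t_res.pvalue)
    empirical = (1 + int((null >= observed).sum())) / (n_draws + 1)
    return MonteCarloResult(
        observed_pct=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        n_draws=n_draws,
        p_value=p_value,
        empirical_percentile=empirical,
        t_statistic=t_stat,
        sample_size=sample_size,
        rng_seed=rng_seed,
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1).

    Invariant under permutation of the input order (values travel with
    their positions).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def ora(
    query: Iterable[str],
    pathways: Sequence[PathwaySet],
    reference: Iterable[str],
) -> list[ORAResult]:
    """One-sided over-representation analysis of *query* against *pathways*.

    Query symbols outside the reference are dropped with a warning;
    pathway members are intersected with the reference, and pathways with
    no member in the reference are skipped.  The p-value is the
    hypergeometric upper tail P(X >= k) for drawing ``n`` genes from a
    universe of ``N`` containing ``K`` pathway genes; FDR is
    Benjamini–Hochberg across all tested pathways.
    """
    ref = {normalize_symbol(g) for g in reference}
    if not ref:
        raise ValueError("reference universe must be non-empty")
    q_raw = {normalize_symbol(g) for g in query}
    q = q_raw & ref
    n_outside = len(q_raw) - len(q)
    if n_outside:
        logger.warning("dropped %d query gene(s) outside the reference", n_outside)
    if not q:
        raise ValueError("query is empty after intersection with the reference")

    N = len(ref)
    n = len(q)
    results: list[ORAResult] = []
    for pw in pathways:
        members = pw.members & ref
        K = len(members)
        if K == 0:
            logger.info("skipping pathway %r: no member in reference", pw.name)
            continue
        overlap = frozenset(q & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        er = (k / n) / (K / N)
        results.append(
            ORAResult(
                pathway=pw.name,
                overlap_genes=overlap,
                k=k,
                n_list=n,
                K=K,
                N_ref=N,
                p_value=min(p, 1.0),
                fdr=np.nan,
                enrichment_ratio=er,
            )
        )
    fdrs = bh_fdr([r.p_value for r in results])
    return [replace(r, fdr=f) for r, f in zip(results, fdrs)]


def flag_biased(
    significant_counts: Mapping[str, int], min_significant: int = 2
) -> set[str]:
    """Pathways significant in at least *min_significant* random replicates."""
    return {name for name, c in significant_counts.items() if c >= min_significant}


def random_ora_control(
    mapped: Sequence[str],
    list_sizes: Iterable[int],
    pathways: Sequence[PathwaySet],
    reference: Iterable[str],
    n_reps: int = 3,
    rng_seed: int = 0,
    alpha: float = FDR_THRESHOLD,
    min_significant: int = 2,
) -> dict[int, set[str]]:
    """Triplicate random-ORA bias control.

    For each list size, *n_reps* random subsets of the mapped genes are
    drawn without replacement and run through :func:`ora`; a pathway with
    FDR <= *alpha* in at least *min_significant* replicates is flagged as
    biased for that size (its enrichment reflects the composition of the
    input list, not centrality).  Returns ``{size: biased pathway names}``.
    """
    mapped_list = list(dict.fromkeys(normalize_symbol(g) for g in mapped))
    reference = list(reference)
    rng = np.random.default_rng(rng_seed)
    out: dict[int, set[str]] = {}
    for size in list_sizes:
        size = int(size)
        if size < 1 or size > len(mapped_list):
            raise ValueError(f"list size {size} exceeds mapped pool of {len(mapped_list)}")
        counts: Counter[str] = Counter()
        for _ in range(n_reps):
            idx = rng.choice(len(mapped_list), size=size, replace=False)
            subset = {mapped_list[i] for i in idx}
            for res in ora(subset, pathways, reference):
                if res.fdr <= alpha:
                    counts[res.pathway] += 1
        out[size] = flag_biased(counts, min_significant)
    return out


def apply_bias_flags(
    results: Sequence[ORAResult], biased_pathways: Iterable[str]
) -> list[ORAResult]:
    """Return results with ``bias_flag`` set for the named pathways."""
    biased = set(biased_pathways)
    return [replace(r, bias_flag=r.pathway in biased) for r in results]
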