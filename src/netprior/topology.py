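"""Topological metrics: betweenness centrality, ranking, component census.

The central statistic is the normalized betweenness centrality of a node
n_i,

    C_B(n_i) = sum_{j<k} sigma_jk(n_i) / sigma_jk * 2 / ((N-1)(N-2)),

where N is the total node count, sigma_jk the number of geodesics between
n_j and n_k, and sigma_jk(n_i) the number of those geodesics passing
through n_i (endpoints excluded, the standard convention).  The trailing
factor normalizes by the number of node pairs excluding n_i itself, so
values lie in [0,1] for an undirected graph.

Betweenness is computed exactly (no sampling) with the Brandes
shortest-path accumulation, implemented level-synchronously on a sparse
adjacency matrix so that networks of a few thousand nodes are processed
in seconds.  The computation runs on the whole, possibly disconnected,
graph with N equal to the total node count — pairs in different
components simply contribute nothing — so values remain comparable
across components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .network_builder import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CENTRALITY_COLUMNS",
    "ComponentCensus",
    "betweenness",
    "relative_betweenness",
    "rank_by_betweenness",
    "component_census",
    "connected_fraction",
    "metric_correlations",
]

#: column order of a centrality table
CENTRALITY_COLUMNS = ["symbol", "degree", "betweenness", "closeness"]


def _brandes_sparse(adjacency: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Exact betweenness (raw, pair-double-counted) and closeness.

    Per source: a level-synchronous BFS accumulates geodesic counts
    (sigma) going down and dependencies (delta) coming back up, each
    level being one sparse mat-vec.  Returns the Brandes accumulator
    (each unordered pair counted from both endpoints) and the
    component-scaled closeness ``(r-1)/sum(d) * (r-1)/(n-1)`` with r the
    number of reachable nodes.
    """
    n = adjacency.shape[0]
    bc = np.zeros(n)
    closeness = np.zeros(n)
    for s in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        sigma = np.zeros(n)
        dist[s] = 0
        sigma[s] = 1.0
        levels: list[np.ndarray] = [np.array([s], dtype=np.int64)]
        frontier = levels[0]
        d = 0
        while frontier.size:
            x = np.zeros(n)
            x[frontier] = sigma[frontier]
            y = adjacency @ x  # y[v] = sum of sigma over v's neighbors in the frontier
            nxt = np.flatnonzero((dist < 0) & (y > 0))
            if nxt.size == 0:
                break
            d += 1
            dist[nxt] = d
            sigma[nxt] = y[nxt]
            levels.append(nxt)
            frontier = nxt

        # dependency accumulation, deepest level first
        delta = np.zeros(n)
        for depth in range(len(levels) - 1, 0, -1):
            w = levels[depth]
            coeff = np.zeros(n)
            coeff[w] = (1.0 + delta[w]) / sigma[w]
            y = adjacency @ coeff
            prev = levels[depth - 1]
            delta[prev] += sigma[prev] * y[prev]
        delta[s] = 0.0
        bc += delta

        reachable = dist >= 0
        r = int(reachable.sum())
        if r > 1 and n > 1:
            total = float(dist[reachable].sum())
            closeness[s] = (r - 1) / total * (r - 1) / (n - 1)
    return bc, closeness


def betweenness(net: PPINetwork) -> pd.DataFrame:
    """Compute the centrality table of a network.

    Returns a DataFrame with one row per node (symbols sorted) and the
    columns ``symbol``, ``degree``, ``betweenness`` (normalized to [0,1])
    and ``closeness``.  For fewer than three nodes every betweenness is 0
    (the normalizer is degenerate) and a warning is logged.
    """
    nodes = net.sorted_nodes()
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    degree = np.array([net.graph.degree(v) for v in nodes], dtype=np.int64)

    if n < 3:
        logger.warning("betweenness undefined for N < 3 nodes; reporting zeros")
        bc_norm = np.zeros(n)
        closeness = np.zeros(n)
        if n == 2 and net.n_edges == 1:
            closeness[:] = 1.0
    else:
        rows, cols = [], []
        for u, v in net.graph.edges:
            i, j = index[u], index[v]
            rows += [i, j]
            cols += [j, i]
        adjacency = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
        )
        bc_raw, closeness = _brandes_sparse(adjacency)
        # raw accumulator counts each unordered pair twice; combined with the
        # 2/((N-1)(N-2)) normalization this is a single division.
        bc_norm = bc_raw / ((n - 1) * (n - 2))

    return pd.DataFrame(
        {
            "symbol": nodes,
            "degree": degree,
            "betweenness": bc_norm,
            "closeness": closeness,
        },
        columns=CENTRALITY_COLUMNS,
    )


def relative_betweenness(
    table: pd.DataFrame, reference_max: float | None = None
) -> pd.DataFrame:
    """Express betweenness as percent of a reference maximum.

    With no *reference_max*, the table's own maximum is used (that node
    scores 100; ties share it).  A mapped sublist is expressed against
    the FULL network's maximum by passing that value explicitly.  Values
    are reported to two decimals.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    ref = float(table["betweenness"].max()) if reference_max is None else float(reference_max)
    if ref <= 0:
        raise ValueError("no central node: reference maximum betweenness is not positive")
    out = table.copy()
    out["relative_betweenness"] = (100.0 * out["betweenness"] / ref).round(2)
    return out


def rank_by_betweenness(table: pd.DataFrame) -> pd.DataFrame:
    """Sort descending by betweenness, ties broken lexicographically by symbol.

    Adds a 1-based ``rank`` column; the sort is stable and documented so
    downstream quantile cuts are reproducible.
    """
    out = table.sort_values(
        ["betweenness", "symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class ComponentCensus:
    """Multiset of connected-component sizes of a network."""

    sizes: list[int] = field(default_factory=list)  # descending

    def __post_init__(self) -> None:
        self.sizes = sorted((int(s) for s in self.sizes), reverse=True)
        if any(s < 1 for s in self.sizes):
            raise ValueError("component sizes must be positive")

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    @property
    def n_pairs(self) -> int:
        return sum(1 for s in self.sizes if s == 2)

    @property
    def n_triples(self) -> int:
        return sum(1 for s in self.sizes if s == 3)

    @property
    def other_components(self) -> list[int]:
        """Sizes of components with at least four nodes, descending."""
        return [s for s in self.sizes if s >= 4]

    @property
    def total(self) -> int:
        """Sum of all component sizes; equals the node count of the graph."""
        return sum(self.sizes)


def component_census(net: PPINetwork) -> ComponentCensus:
    """Census of connected components (isolated nodes count as singletons)."""
    import networkx as nx

    return ComponentCensus(sizes=[len(c) for c in nx.connected_components(net.graph)])


def connected_fraction(census: ComponentCensus) -> float:
    """Percent of nodes lying in a component of size >= 2, to one decimal."""
    if census.total == 0:
        raise ValueError("empty census")
    return round(100.0 * (census.total - census.n_singletons) / census.total, 1)


def metric_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among betweenness, degree, closeness.

    Returns a symmetric 3x3 DataFrame with unit diagonal; a metric that is
    constant across nodes has undefined correlations, reported as NaN.
    """
    metrics = ["betweenness", "degree", "closeness"]
    if len(table) < 3:
        raise ValueError("need at least 3 nodes for metric correlations")
    values = table[metrics].to_numpy(dtype=float)
    out = np.eye(len(metrics))
    for i in range(len(metrics)):
        for j in range(i + 1, len(metrics)):
            xi, xj = values[:, i], values[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(xi, xj).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=metrics, columns=metrics)
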