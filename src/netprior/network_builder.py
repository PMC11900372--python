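"""Build a seed-anchored interaction network from a raw edge table.

The construction mirrors the two-round database query used to assemble a
disease network: (1) retrieve all interactions of the seed genes, giving
the seeds' first interactors; (2) re-query with seeds plus first
interactors to pick up interactions *among* first interactors; then prune
second interactors (neighbors of neighbors only).  The whole procedure is
equivalent to taking the induced simple subgraph of the full interaction
graph on ``seeds ∪ neighbors(seeds)``, which is what :func:`build_seed_network`
computes; the equivalence is exercised against a literal two-round oracle
in the test suite.

Upstream of that, rows are filtered to a single taxon (homology
inferences out), identifiers are collapsed to gene symbols via an alias
map (so distinct accessions of one protein do not create phantom
parallel edges), and self-loops and duplicate edges are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import (
    GeneRecord,
    InteractionRecord,
    looks_like_uniprot,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "filter_taxon",
    "collapse_to_symbols",
    "build_seed_network",
    "extract_subnetwork",
    "write_network",
    "read_network",
]

HUMAN_TAXON = 9606


@dataclass
class PPINetwork:
    """An undirected simple graph of gene symbols with seed annotations.

    Invariants: no self-loops, no duplicate edges, every edge endpoint in
    the node set.  ``node_tags`` maps each symbol to
    ``{"is_seed": bool, "seed_score": int|None, "syndromic": bool|None}``.
    ``provenance`` records build parameters and bookkeeping counts.
    """

    graph: nx.Graph
    node_tags: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed in PPINetwork: {loops[:3]}")
        for node in self.graph.nodes:
            self.node_tags.setdefault(
                node, {"is_seed": False, "seed_score": None, "syndromic": None}
            )

    @property
    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def seeds(self) -> list[str]:
        return sorted(n for n, t in self.node_tags.items() if t.get("is_seed"))


def filter_taxon(
    records: Iterable[InteractionRecord], taxon: int = HUMAN_TAXON
) -> list[InteractionRecord]:
    """Keep only records where both interactors belong to *taxon*.

    Removes cross-species rows and homology-inferred interactions.  An
    empty result is allowed (with a warning).
    """
    kept = [r for r in records if r.taxon_a == taxon and r.taxon_b == taxon]
    if not kept:
        logger.warning("taxon filter %d removed every record", taxon)
    return kept


def collapse_to_symbols(
    records: Iterable[InteractionRecord],
    alias_map: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str]], int]:
    """Map raw interactor IDs to gene symbols and canonicalize pairs.

    Each identifier is looked up in *alias_map* (e.g. UniProt accession →
    symbol).  Identifiers absent from the map pass through as symbols
    unless they look like UniProt accessions, in which case the record is
    dropped and counted.  Pairs are ordered lexicographically and
    deduplicated (collapsing aliases is exactly what removes redundant
    parallel edges).  Self-loop pairs are retained here; they are removed
    when the graph is built.

    Returns ``(unique_pairs, n_dropped_records)``.
    """
    alias_map = alias_map or {}

    def to_symbol(identifier: str) -> str | None:
        identifier = identifier.strip()
        if identifier in alias_map:
            return alias_map[identifier]
        if looks_like_uniprot(identifier):
            return None
        return normalize_symbol(identifier)

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    n_duplicates = 0
    for record in records:
        a = to_symbol(record.id_a)
        b = to_symbol(record.id_b)
        if a is None or b is None or not a or not b:
            n_dropped += 1
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in seen:
            n_duplicates += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    if n_dropped:
        logger.warning("dropped %d record(s) with unmappable identifiers", n_dropped)
    if n_duplicates:
        logger.info("collapsed %d duplicate pair(s)", n_duplicates)
    return pairs, n_dropped


def build_seed_network(
    pairs: Iterable[tuple[str, str]], seeds: Sequence[GeneRecord]
) -> PPINetwork:
    """Construct the seed-anchored network from symbol pairs.

    The node set is ``seeds ∪ neighbors(seeds)`` in the full interaction
    graph; the edge set is the induced simple subgraph, which includes
    every seed–interactor edge and every edge among first interactors
    while excluding second interactors.  Seeds without any interaction
    are retained as isolated nodes.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed list must be non-empty")

    full = nx.Graph()
    n_self_loops = 0
    n_pairs_in = 0
    for a, b in pairs:
        a, b = normalize_symbol(a), normalize_symbol(b)
        n_pairs_in += 1
        if a == b:
            n_self_loops += 1
            continue
        full.add_edge(a, b)

    seed_symbols = sorted({s.symbol for s in seeds})
    keep: set[str] = set(seed_symbols)
    for s in seed_symbols:
        if s in full:
            keep.update(full.neighbors(s))

    graph = nx.Graph()
    graph.add_nodes_from(sorted(keep))
    graph.add_edges_from(
        sorted(
            tuple(sorted((u, v)))
            for u, v in full.edges
            if u in keep and v in keep
        )
    )

    tags: dict[str, dict] = {}
    by_symbol = {s.symbol: s for s in seeds}
    for node in graph.nodes:
        rec = by_symbol.get(node)
        tags[node] = {
            "is_seed": rec is not None,
            "seed_score": rec.seed_score if rec else None,
            "syndromic": rec.syndromic if rec else None,
        }
    provenance = {
        "n_input_pairs": n_pairs_in,
        "n_self_loops_removed": n_self_loops,
        "n_seeds": len(seed_symbols),
        "n_isolated_seeds": sum(1 for s in seed_symbols if graph.degree(s) == 0),
        "construction": "induced subgraph on seeds and first interactors",
    }
    return PPINetwork(graph=graph, node_tags=tags, provenance=provenance)


def extract_subnetwork(
    net: PPINetwork, genes: Iterable[str]
) -> tuple[PPINetwork, list[str]]:
    """Induced subgraph on ``genes ∩ net.nodes``; absent genes reported.

    Returns ``(subnetwork, unmapped)`` where *unmapped* is the sorted list
    of requested symbols not present in the network.
    """
    wanted = {normalize_symbol(g) for g in genes}
    present = wanted & net.node_set
    unmapped = sorted(wanted - present)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(present))
    sub.add_edges_from(
        sorted(
            tuple(sorted((u, v)))
            for u, v in net.graph.edges
            if u in present and v in present
        )
    )
    tags = {n: dict(net.node_tags[n]) for n in sub.nodes}
    provenance = dict(net.provenance)
    provenance.update(
        {"extracted_from": net.n_nodes, "n_requested": len(wanted), "n_unmapped": len(unmapped)}
    )
    return PPINetwork(graph=sub, node_tags=tags, provenance=provenance), unmapped


# ---------------------------------------------------------------------------
# persistence (edge-list TSV + node-table TSV)


def write_network(net: PPINetwork, edges_path: str | Path, nodes_path: str | Path) -> None:
    pd.DataFrame(net.sorted_edges(), columns=["id_a", "id_b"]).to_csv(
        edges_path, sep="\t", index=False
    )
    rows = []
    for node in net.sorted_nodes():
        t = net.node_tags[node]
        rows.append(
            {
                "symbol": node,
                "is_seed": int(bool(t.get("is_seed"))),
                "seed_score": "" if t.get("seed_score") is None else str(t["seed_score"]),
                "syndromic": "" if t.get("syndromic") is None else str(int(t["syndromic"])),
                "degree": net.graph.degree(node),
            }
        )
    pd.DataFrame(rows, columns=["symbol", "is_seed", "seed_score", "syndromic", "degree"]).to_csv(
        nodes_path, sep="\t", index=False
    )


def read_network(edges_path: str | Path, nodes_path: str | Path | None = None) -> PPINetwork:
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    graph = nx.Graph()
    for _, row in edges.iterrows():
        a, b = normalize_symbol(row["id_a"]), normalize_symbol(row["id_b"])
        if a != b:
            graph.add_edge(a, b)
    tags: dict[str, dict] = {}
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
        for _, row in nodes.iterrows():
            symbol = normalize_symbol(row["symbol"])
            graph.add_node(symbol)
            score = row.get("seed_score")
            synd = row.get("syndromic")
            tags[symbol] = {
                "is_seed": str(row.get("is_seed", "0")).strip() in ("1", "True", "true"),
                "seed_score": int(score) if isinstance(score, str) and score.strip() else None,
                "syndromic": bool(int(synd)) if isinstance(synd, str) and synd.strip() else None,
            }
    return PPINetwork(graph=graph, node_tags=tags, provenance={"read_from": str(edges_path)})
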