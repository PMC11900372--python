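"""Synthetic inputs with the statistical structure the method assumes.

Every external input of the pipeline can be generated here so that each
stage is testable without database downloads:

* a scale-free (preferential-attachment) interactome whose degree
  heterogeneity mimics an undirected biological network, with a planted
  disease module — the seed genes plus companions — wired densely among
  themselves and given long-range edges so the module occupies the top
  of the betweenness distribution (the structure a centrality-based
  prioritizer assumes);
* an edge table over UniProt-style accessions with an alias map back to
  symbols, contaminated with a configurable fraction of non-human-taxon
  rows and unmappable accessions, plus a few duplicate rows and
  self-loops, exercising every cleaning step;
* a candidate gene list mixing planted module genes, background network
  genes and non-coding-style decoys that cannot map onto the network;
* GMT pathway sets including one pathway over-sampled from the candidate
  list at a configurable enrichment fold;
* a genes × brain-regions TPM matrix with a planted co-expressed block.

Everything is deterministic given ``FixtureSpec.rng_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .io_formats import (
    ExpressionMatrix,
    GeneRecord,
    InteractionRecord,
    PathwaySet,
    write_alias_map,
    write_edge_table,
    write_expression,
    write_gene_list,
    write_gmt,
)
from .network_builder import build_seed_network, collapse_to_symbols, filter_taxon

__all__ = ["FixtureSpec", "Fixtures", "make_interactome", "make_pathways", "make_expression", "generate_fixtures", "write_fixtures"]

#: region names used when the spec asks for exactly 13 regions
BRAIN_REGIONS_13 = [
    "amygdala",
    "basal_ganglia",
    "cerebellum",
    "cerebral_cortex",
    "choroid_plexus",
    "hippocampal_formation",
    "hypothalamus",
    "medulla_oblongata",
    "midbrain",
    "pons",
    "spinal_cord",
    "thalamus",
    "white_matter",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data generator.

    Defaults emulate the shapes of the real study at desk scale: a
    2000-gene interactome inside a 6000-symbol protein-coding universe,
    60 seed genes, a 768-symbol candidate list of which 456 lie in the
    network, 20 pathways with one planted at 10-fold enrichment, and
    expression over 13 brain regions with a co-expressed block at r=0.8.
    """

    n_genes: int = 2000  # interactome size
    universe_extra: int = 4000  # universe-only symbols beyond the interactome
    n_seed_genes: int = 60
    attachment: int = 3  # preferential-attachment edges per new node
    planted_module_size: int = 80  # seeds plus companion disease genes
    module_density: float = 0.15  # intra-module wiring probability
    module_hub_edges: int = 60  # long-range edges per module gene
    n_candidates: int = 768
    n_candidates_mapped: int = 456  # candidates that lie in the seed network
    candidate_planted_fraction: float = 0.15  # of mapped candidates from the module
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_pathway_size: int = 30
    planted_enrichment_fold: float = 10.0
    n_regions: int = 13
    coexpression_block_size: int = 30
    block_correlation: float = 0.8
    frac_nonhuman_edges: float = 0.10  # fraction of edge rows with a foreign taxon
    frac_unmappable_ids: float = 0.05  # fraction of clean rows with an unknown accession
    n_duplicate_rows: int = 5
    n_self_loop_rows: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_genes >= 10, "n_genes must be at least 10"),
            (self.universe_extra >= 0, "universe_extra must be non-negative"),
            (0 < self.n_seed_genes <= self.planted_module_size,
             "n_seed_genes must be positive and at most planted_module_size"),
            (self.planted_module_size <= self.n_genes,
             "planted_module_size must not exceed n_genes"),
            (1 <= self.attachment < self.n_genes, "attachment must be in [1, n_genes)"),
            (0 <= self.module_density <= 1, "module_density must be in [0, 1]"),
            (self.module_hub_edges >= 0, "module_hub_edges must be non-negative"),
            (0 < self.n_candidates_mapped <= self.n_candidates,
             "n_candidates_mapped must be positive and at most n_candidates"),
            (0 <= self.candidate_planted_fraction <= 1,
             "candidate_planted_fraction must be in [0, 1]"),
            (round(self.candidate_planted_fraction * self.n_candidates_mapped)
             <= self.planted_module_size,
             "planted candidates cannot exceed planted_module_size"),
            (self.n_pathways >= 1, "n_pathways must be positive"),
            (1 <= self.pathway_size_range[0] <= self.pathway_size_range[1],
             "pathway_size_range must be an increasing positive pair"),
            (self.planted_pathway_size >= 1, "planted_pathway_size must be positive"),
            (self.planted_enrichment_fold > 0, "planted_enrichment_fold must be positive"),
            (self.n_regions >= 2, "n_regions must be at least 2"),
            (0 < self.coexpression_block_size <= self.n_genes,
             "coexpression_block_size must be in (0, n_genes]"),
            (0 <= self.block_correlation < 1, "block_correlation must be in [0, 1)"),
            (0 <= self.frac_nonhuman_edges < 1, "frac_nonhuman_edges must be in [0, 1)"),
            (0 <= self.frac_unmappable_ids < 1, "frac_unmappable_ids must be in [0, 1)"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)


@dataclass
class Fixtures:
    """All generated inputs plus ground-truth bookkeeping."""

    spec: FixtureSpec
    edge_records: list[InteractionRecord]
    alias_map: dict[str, str]
    seed_records: list[GeneRecord]
    candidate_records: list[GeneRecord]
    universe: list[str]
    pathways: list[PathwaySet]
    expression: ExpressionMatrix
    truth: dict = field(default_factory=dict)


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _accession(i: int) -> str:
    # valid UniProt-style accession mapped in the alias table
    return f"P{i:05d}"


def _bad_accession(j: int) -> str:
    # valid UniProt shape, guaranteed absent from the alias table
    return f"O{j:05d}"


def make_interactome(
    spec: FixtureSpec,
) -> tuple[list[InteractionRecord], dict[str, str], list[GeneRecord], dict]:
    """Generate the edge table, alias map and seed list.

    Returns ``(edge_records, alias_map, seed_records, truth)`` where
    *truth* records the planted module, the clean symbol graph, the seed
    network node set and the contamination bookkeeping counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_symbols(spec.n_genes)

    base = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(base, dict(enumerate(genes)))

    module = sorted(
        rng.choice(spec.n_genes, size=spec.planted_module_size, replace=False)
    )
    module_genes = [genes[i] for i in module]
    # dense intra-module wiring
    for ai in range(len(module_genes)):
        for bi in range(ai + 1, len(module_genes)):
            if rng.random() < spec.module_density:
                graph.add_edge(module_genes[ai], module_genes[bi])
    # long-range edges give the module its elevated betweenness
    for g in module_genes:
        targets = rng.choice(spec.n_genes, size=spec.module_hub_edges, replace=False)
        for t in targets:
            if genes[t] != g:
                graph.add_edge(g, genes[t])

    seed_idx = sorted(rng.choice(len(module_genes), size=spec.n_seed_genes, replace=False))
    seed_records = []
    for i in seed_idx:
        # roughly the real study's score-1:score-2 input mix (~15% high confidence)
        score = 1 if rng.random() < 0.15 else 2
        seed_records.append(
            GeneRecord(symbol=module_genes[i], seed_score=score, syndromic=False)
        )

    alias_map = {_accession(i): genes[i] for i in range(spec.n_genes)}
    acc_of = {genes[i]: _accession(i) for i in range(spec.n_genes)}

    clean_edges = sorted(tuple(sorted(e)) for e in graph.edges)
    n_clean = len(clean_edges)

    # corrupt a fraction of rows with accessions absent from the alias map
    n_unmappable = int(np.floor(spec.frac_unmappable_ids * n_clean))
    corrupt_idx = set(
        rng.choice(n_clean, size=n_unmappable, replace=False).tolist()
    )

    rows: list[InteractionRecord] = []
    for i, (a, b) in enumerate(clean_edges):
        id_a, id_b = acc_of[a], acc_of[b]
        if i in corrupt_idx:
            id_a = _bad_accession(i)
        if rng.random() < 0.5:
            id_a, id_b = id_b, id_a
        rows.append(
            InteractionRecord(id_a=id_a, id_b=id_b, taxon_a=9606, taxon_b=9606, source="synthetic")
        )

    # duplicate a few clean rows and add self-loops (removed downstream)
    clean_row_idx = [i for i in range(n_clean) if i not in corrupt_idx]
    for i in rng.choice(clean_row_idx, size=min(spec.n_duplicate_rows, len(clean_row_idx)), replace=False):
        rows.append(dataclasses.replace(rows[int(i)]))
    for i in rng.choice(spec.n_genes, size=spec.n_self_loop_rows, replace=False):
        acc = _accession(int(i))
        rows.append(
            InteractionRecord(id_a=acc, id_b=acc, taxon_a=9606, taxon_b=9606, source="synthetic")
        )
    n_human_rows = len(rows)

    # foreign-taxon contamination (removed exactly by the taxon filter)
    n_foreign = int(round(spec.frac_nonhuman_edges / (1 - spec.frac_nonhuman_edges) * n_human_rows)) if spec.frac_nonhuman_edges else 0
    foreign_taxa = [(9606, 10090), (10090, 10090), (9606, 7227)]
    for j in range(n_foreign):
        a, b = rng.choice(spec.n_genes, size=2, replace=False)
        ta, tb = foreign_taxa[j % len(foreign_taxa)]
        rows.append(
            InteractionRecord(
                id_a=_accession(int(a)), id_b=_accession(int(b)),
                taxon_a=ta, taxon_b=tb, source="synthetic-foreign",
            )
        )

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    # derive the seed network through the package's own cleaning path
    human = filter_taxon(rows, 9606)
    pairs, n_dropped = collapse_to_symbols(human, alias_map)
    net = build_seed_network(pairs, seed_records)

    truth = {
        "module_genes": module_genes,
        "seed_symbols": [r.symbol for r in seed_records],
        "n_clean_rows": n_human_rows,
        "n_foreign_rows": n_foreign,
        "n_unmappable_rows": n_unmappable,
        "n_dropped_at_collapse": n_dropped,
        "clean_graph_edges": clean_edges,
        "network_nodes": sorted(net.node_set),
    }
    return rows, alias_map, seed_records, truth


def _make_candidates(
    spec: FixtureSpec, truth: dict, rng: np.random.Generator
) -> tuple[list[GeneRecord], dict]:
    network_nodes = set(truth["network_nodes"])
    module = [g for g in truth["module_genes"] if g in network_nodes]
    background_pool = sorted(network_nodes - set(module))
    n_planted = int(round(spec.candidate_planted_fraction * spec.n_candidates_mapped))
    n_background = spec.n_candidates_mapped - n_planted
    if n_planted > len(module):
        raise ValueError(
            f"planted candidate count {n_planted} exceeds in-network module size {len(module)}"
        )
    if n_background > len(background_pool):
        raise ValueError(
            f"background candidate count {n_background} exceeds non-module network "
            f"pool of {len(background_pool)}; enlarge the interactome or seed set"
        )
    planted = [module[i] for i in rng.choice(len(module), size=n_planted, replace=False)]
    background = [
        background_pool[i]
        for i in rng.choice(len(background_pool), size=n_background, replace=False)
    ]
    decoys = [f"NC{i:04d}" for i in range(spec.n_candidates - spec.n_candidates_mapped)]
    symbols = planted + background + decoys
    order = rng.permutation(len(symbols))
    records = [GeneRecord(symbol=symbols[i]) for i in order]
    truth_update = {
        "planted_candidates": sorted(planted),
        "background_candidates": sorted(background),
        "decoy_candidates": decoys,
    }
    return records, truth_update


def make_pathways(
    spec: FixtureSpec,
    gene_universe: Sequence[str],
    candidate_symbols: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[PathwaySet]:
    """Random pathway sets plus one planted enriched pathway.

    The planted pathway over-samples the candidate list so that its
    expected enrichment ratio against the universe equals roughly
    ``planted_enrichment_fold``; at fold 1 it is statistically indistinct
    from the random pathways (a null-calibration input).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    universe = list(gene_universe)
    lo, hi = spec.pathway_size_range
    pathways: list[PathwaySet] = []
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        pathways.append(
            PathwaySet(
                name=f"PATHWAY_{i:02d}",
                description="synthetic random pathway",
                members=frozenset(universe[j] for j in idx),
            )
        )
    if candidate_symbols is not None:
        cand = sorted(set(candidate_symbols) & set(universe))
        rest = sorted(set(universe) - set(cand))
        base_rate = len(cand) / len(universe)
        p_in = min(0.95, spec.planted_enrichment_fold * base_rate)
        k_in = min(int(round(p_in * spec.planted_pathway_size)), len(cand))
        k_out = spec.planted_pathway_size - k_in
        members = [cand[i] for i in rng.choice(len(cand), size=k_in, replace=False)]
        members += [rest[i] for i in rng.choice(len(rest), size=k_out, replace=False)]
        pathways.append(
            PathwaySet(
                name="PLANTED_PATHWAY",
                description=f"synthetic pathway enriched {spec.planted_enrichment_fold}x in the candidate list",
                members=frozenset(members),
            )
        )
    return pathways


def make_expression(
    spec: FixtureSpec,
    genes: Sequence[str],
    block_genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-normal TPM baseline with a planted co-expressed block.

    Each gene's log2-TPM profile across regions is its own mean plus
    unit-variance noise; block genes share a latent regional profile with
    weight sqrt(r), giving pairwise correlation ~``block_correlation``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    genes = list(genes)
    block = set(block_genes or [])
    n, m = len(genes), spec.n_regions
    regions = BRAIN_REGIONS_13 if m == 13 else [f"region_{i:02d}" for i in range(m)]

    mu = rng.normal(3.0, 1.5, size=n)  # per-gene baseline on the log2 scale
    latent = rng.normal(0.0, 1.0, size=m)  # shared regional profile of the block
    noise = rng.normal(0.0, 1.0, size=(n, m))
    r = spec.block_correlation
    log_expr = mu[:, None] + noise
    is_block = np.array([g in block for g in genes])
    if is_block.any():
        log_expr[is_block] = (
            mu[is_block, None]
            + np.sqrt(r) * latent[None, :]
            + np.sqrt(1.0 - r) * noise[is_block]
        )
    tpm = np.exp2(log_expr)

    import pandas as pd

    return ExpressionMatrix(values=pd.DataFrame(tpm, index=genes, columns=regions))


def generate_fixtures(spec: FixtureSpec | None = None) -> Fixtures:
    """Generate the complete, mutually consistent set of inputs."""
    spec = spec or FixtureSpec()
    spec.validate()
    edge_records, alias_map, seed_records, truth = make_interactome(spec)
    # streams for the remaining components are derived from the same seed
    rng = np.random.default_rng((spec.rng_seed, 1))

    candidates, truth_update = _make_candidates(spec, truth, rng)
    truth.update(truth_update)

    genes = _gene_symbols(spec.n_genes)
    universe = genes + [f"U{i:04d}" for i in range(spec.universe_extra)]

    mapped = sorted(
        set(truth["planted_candidates"]) | set(truth["background_candidates"])
    )
    pathways = make_pathways(spec, universe, candidate_symbols=mapped, rng=rng)
    truth["planted_pathway"] = "PLANTED_PATHWAY"

    block = truth["module_genes"][: spec.coexpression_block_size]
    expression = make_expression(spec, genes, block_genes=block, rng=rng)
    truth["coexpression_block"] = list(block)

    return Fixtures(
        spec=spec,
        edge_records=edge_records,
        alias_map=alias_map,
        seed_records=seed_records,
        candidate_records=candidates,
        universe=universe,
        pathways=pathways,
        expression=expression,
        truth=truth,
    )


def write_fixtures(fixtures: Fixtures, out_dir: str | Path) -> dict[str, Path]:
    """Materialize every fixture as TSV/GMT files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "aliases": out / "aliases.tsv",
        "seeds": out / "seeds.tsv",
        "candidates": out / "candidates.tsv",
        "universe": out / "universe.tsv",
        "pathways": out / "pathways.gmt",
        "expression": out / "expression.tsv",
    }
    write_edge_table(fixtures.edge_records, paths["edges"])
    write_alias_map(fixtures.alias_map, paths["aliases"])
    write_gene_list(fixtures.seed_records, paths["seeds"])
    write_gene_list(fixtures.candidate_records, paths["candidates"])
    write_gene_list([GeneRecord(symbol=g) for g in fixtures.universe], paths["universe"])
    write_gmt(fixtures.pathways, paths["pathways"])
    write_expression(fixtures.expression, paths["expression"])
    return paths
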