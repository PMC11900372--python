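# netprior

Seed-anchored protein–protein interaction (PPI) networks and
betweenness-centrality gene prioritization for noisy candidate lists.

## The problem

Candidate-gene lists from copy-number-variant (CNV) screens, exome panels
or GWAS follow-ups are large and noisy: most entries are variants of
uncertain significance, and expression or literature evidence is often
missing. `netprior` implements a network strategy for triaging such
lists. Starting from a curated set of *seed* disease genes (e.g. genes
scored 1–3 in a confidence-tiered database, with a separate syndromic
flag), it:

1. **builds a seed-anchored PPI network** from an interaction edge table:
   rows are filtered to one taxon (9606 by default, removing homology
   inferences), identifiers are collapsed to gene symbols via an alias
   map so accession aliases do not create phantom parallel edges,
   duplicate edges and self-loops are removed, and the network is
   restricted to the seeds and their first interactors — including the
   edges *among* first interactors, excluding second interactors;
2. **ranks every node by normalized betweenness centrality**

   $$C_B(n_i) = \sum_{j<k} \frac{\sigma_{jk}(n_i)}{\sigma_{jk}} \cdot \frac{2}{(N-1)(N-2)},$$

   where $N$ is the node count, $\sigma_{jk}$ the number of geodesics
   between $n_j$ and $n_k$, and $\sigma_{jk}(n_i)$ those passing through
   $n_i$ — computed exactly with the Brandes accumulation, plus degree
   and closeness as companion metrics and a connected-component census;
3. **validates the network** by Monte-Carlo resampling: the fraction of a
   seed category covered by the network is compared with equally sized
   random draws from the gene universe (one-sample t-test plus an
   empirical percentile);
4. **maps a candidate list onto the network**, ranks the mapped genes by
   the full network's betweenness, expresses each as a percent of the
   network maximum, annotates TPM expression classes
   (low &lt;10, medium 10–50, high &gt;50), and cuts top-80/50/20%
   sublists by the floor rule;
5. **characterizes the sublists by over-representation analysis** (ORA):
   one-sided Fisher exact test against GMT pathway sets with
   Benjamini–Hochberg FDR and enrichment ratios, plus a triplicate
   random-ORA control that flags pathways significant in ≥2 of 3
   size-matched random lists as input-composition biases rather than
   centrality-driven signal;
6. optionally **correlates expression profiles** of the top-ranked genes
   with a reference gene set across brain regions (Pearson on
   log2(TPM+1) by default).

A synthetic-data module generates all six inputs — a scale-free
interactome with a planted disease module, contaminated edge tables,
candidate lists, pathway sets with a planted enrichment, and expression
matrices with a planted co-expressed block — so the entire pipeline is
testable without any database download.

## Worked example

```python
from netprior import (FixtureSpec, generate_fixtures, filter_taxon,
                      collapse_to_symbols, build_seed_network, betweenness,
                      relative_betweenness, map_candidates, quantile_sublists,
                      seed_fraction)

fx = generate_fixtures(FixtureSpec(rng_seed=1))
human = filter_taxon(fx.edge_records, taxon=9606)
pairs, dropped = collapse_to_symbols(human, fx.alias_map)
net = build_seed_network(pairs, fx.seed_records)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges "
      f"({dropped} unmappable rows dropped)")

table = relative_betweenness(betweenness(net))
prioritized, unmapped = map_candidates(net, table, fx.candidate_records)
print(f"candidates mapped: {len(prioritized)} of {len(prioritized) + len(unmapped)}")
sizes = {p: len(g) for p, g in quantile_sublists(prioritized, [0.8, 0.5, 0.2]).items()}
print(f"sublist sizes: {sizes}")
print(f"seed fraction of top 30: {seed_fraction(prioritized, 30)}%")
```

prints

```
network: 1696 nodes, 9068 edges (561 unmappable rows dropped)
candidates mapped: 456 of 768
sublist sizes: {0.8: 364, 0.5: 228, 0.2: 91}
seed fraction of top 30: 97%
```

The 1696-node network is the seeds plus their first interactors after
cleaning; of the 768 synthetic candidates only the 456 protein-coding
network members map (the rest mimic pseudogene/non-coding entries), the
floor rule cuts them into 364/228/91-gene sublists, and 97% of the top
30 mapped genes carry a seed annotation because the generator plants the
disease module at the top of the betweenness distribution.

The same pipeline is available from the shell:

```bash
netprior fixtures --out-dir fx --seed 1
netprior build --edges fx/edges.tsv --seeds fx/seeds.tsv --aliases fx/aliases.tsv \
               --out-edges netA_edges.tsv --out-nodes netA_nodes.tsv
netprior rank --edges netA_edges.tsv --nodes netA_nodes.tsv --out centrality.tsv
netprior prioritize --edges netA_edges.tsv --nodes netA_nodes.tsv \
                    --centrality centrality.tsv --candidates fx/candidates.tsv \
                    --out prioritized.tsv
netprior ora --query prioritized.tsv --gmt fx/pathways.gmt \
             --reference fx/universe.tsv --random-control --sizes 364,228,91 \
             --seed 17 --out ora.tsv
```

Real data drop in the same way: any edge table with `id_a`/`id_b` (and
optional taxon) columns, any TSV gene lists, any GMT pathway file.

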