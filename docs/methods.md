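# Methods

## Network construction

The input is a flat interaction table (minimal PSI-MI-TAB-like columns:
two interactor identifiers, two NCBI taxon IDs, an optional source
label) plus a seed gene list with confidence tiers (score 1/2/3 and a
syndromic flag). Construction proceeds in four deterministic steps:

1. **Taxon filter.** Only rows with both taxa equal to the requested
   taxon (default 9606) survive; cross-species rows are typically
   homology inferences and are removed before any topology is computed.
2. **Alias collapse.** Identifiers are mapped to gene symbols through a
   two-column alias table. Distinct accessions of one protein collapse
   to one symbol, which is precisely what removes redundant parallel
   edges. Identifiers absent from the alias map pass through when they
   do not have the shape of a UniProt accession (they are then assumed
   to already be symbols) and are dropped with a count otherwise. This
   unmapped policy is a package choice; the drop count is reported so a
   user can judge the loss.
3. **Simplification.** Pairs are ordered lexicographically,
   deduplicated, and self-loops discarded at graph build time.
4. **Seed anchoring.** The network is the induced simple subgraph on
   `seeds ∪ neighbors(seeds)`. This one-step construction is equivalent
   to the two-round query used with interaction databases (query seeds →
   first interactors; re-query everything → edges among first
   interactors; prune second interactors): round one contributes the
   seed–interactor edges, round two the interactor–interactor edges, and
   pruning removes exactly the nodes outside `seeds ∪ neighbors(seeds)`.
   The test suite checks this equivalence against a literal two-round
   oracle on random graphs up to 200 nodes. Seeds without any
   interaction are kept as isolated nodes — they are members of the
   network and must appear in the component census. Seed–seed edges need
   no special case under the induced-subgraph formulation.

Edge attributes (detection method, publication) are not carried past
provenance counting: the method uses the binary physical-interaction
relation only.

## Betweenness centrality and ranking

For node $n_i$ in a graph with $N$ nodes,

$$C_B(n_i) = \sum_{j<k} \frac{\sigma_{jk}(n_i)}{\sigma_{jk}} \cdot \frac{2}{(N-1)(N-2)},$$

with $\sigma_{jk}$ the geodesic count between $n_j,n_k$ and
$\sigma_{jk}(n_i)$ the count of those geodesics passing through $n_i$,
endpoints excluded (the standard convention). The normalization
$2/((N-1)(N-2))$ — the number of node pairs excluding $n_i$ — keeps
values in $[0,1]$ for undirected graphs and matches the NetworkAnalyzer
convention.

Computation is exact (no sampling): the Brandes accumulation implemented
level-synchronously on a sparse adjacency matrix, one BFS per source
with one sparse mat-vec per BFS level going down (geodesic counts) and
one per level coming back (dependencies). A 2,000-node network is
processed in well under a second; the result agrees with a brute-force
all-geodesics enumeration to 1e−9 on random graphs up to 60 nodes and
with an independent library implementation to 1e−12 on larger ones.
Closeness is read off the same BFS distances with component scaling;
degree comes from the adjacency.

Choices worth stating:

* Betweenness is computed on the whole, possibly disconnected, graph
  with $N$ = total node count, never per component, so values are
  comparable across components of a mapped sublist. Pairs in different
  components contribute nothing.
* Graphs with $N<3$ have a degenerate normalizer; all betweenness is
  reported as 0 with a warning.
* **Relative betweenness** is `100 × b / reference_max`, reported to two
  decimals. The reference defaults to the table's own maximum; a mapped
  sublist should pass the full network's maximum explicitly.
* **Ranking** sorts descending by betweenness with lexicographic
  tie-break — a documented convention, stable under permutation of the
  input, not a claim about any particular published ordering.
* **Quantile sublists** take the first `floor(p·n)` genes (with a 1e−9
  epsilon so `0.2 × 455` floors to 91, not 90). The floor rule is fixed
  by the arithmetic it must reproduce: 456 × 0.8 → 364 and
  456 × 0.2 → 91.
* **TPM classes**: low < 10 ≤ medium ≤ 50 < high; both boundaries fall
  in the middle class, matching the printed "10–50" range.

## Monte-Carlo seed-enrichment validation

Given a gene universe (e.g. HGNC protein-coding symbols), the network's
node set, and a seed category, the observed statistic is the percent of
the category present among the nodes. The null draws `|network|` genes
without replacement from the universe `n_draws` times (default 1000) and
records the category coverage of each draw. The p-value is a two-sided
one-sample t-test of the null draws against the observed value. The t
approximation is aggressive at extreme observations, so the empirical
percentile `(1 + #draws ≥ observed)/(n_draws + 1)` is always reported
next to it; with 1000 draws it cannot be smaller than ~1e−3, which is
why both numbers are given. If every draw is identical (degenerate
null), the t-test is undefined and the p-value is reported as 1 when the
observation equals the constant and 0 otherwise. The RNG (NumPy
Generator, PCG64) and seed are recorded in the result.

## Over-representation analysis

For query size $n$, pathway size $K$ (after intersecting with the
reference universe of size $N$) and overlap $k$, the p-value is the
one-sided hypergeometric upper tail $P(X \ge k)$ — the over-representation
direction of the Fisher exact test, which is what ORA semantics call
for. FDR is Benjamini–Hochberg across all tested pathways (pathways with
no member in the reference are skipped, not tested at p=1). The
enrichment ratio is $(k/n)/(K/N)$. Query symbols outside the reference
are dropped with a warning; the reference universe is a required user
input because "protein-coding genome" sizes are annotation-release
dependent.

The **random-ORA bias control** draws, for each sublist size, three
random subsets of the mapped gene list (the mapped pool is the default;
a different pool can be supplied), runs ORA on each, and flags any
pathway with FDR ≤ 0.05 in at least two of the three replicates. Such a
pathway is enriched because of what the input list contains (e.g. a CNV
region fully covered by one syndrome gene set), not because of node
centrality, and its flag propagates into the corresponding real-sublist
results. Replicate count and the 2-of-3 threshold are configurable.

## Expression correlation

Pearson correlation between each (reference gene, top gene) pair across
regions, computed on log2(TPM+1) by default — TPM spans four orders of
magnitude, and the log keeps single high-expression regions from
dominating — with a raw-TPM mode available. Genes missing from the
matrix are dropped and reported; zero-variance profiles produce NaN
correlations rather than errors, and per-gene medians exclude NaNs. At
least two regions are required; 13 brain regions is the default fixture
header but any region set works.

## Synthetic data generator

The generator emulates the *shapes and planted structure* the method
assumes, not real interactome topology:

* **Interactome**: a Barabási–Albert preferential-attachment graph
  (degree heterogeneity: few hubs, many leaves, as observed in
  undirected biological networks), default 2,000 genes, attachment 3.
* **Planted disease module**: 80 genes (60 of them seeds, scored 1 or 2
  at roughly the 15/85 mix of a confidence-tiered input list,
  non-syndromic) wired together at density 0.15 and each given 60
  long-range edges to uniform random targets. The long-range edges make
  the module genes bridges between graph regions, i.e. they occupy the
  top of the betweenness distribution — exactly the structure a
  centrality-based prioritizer assumes about disease genes and their
  partners. This is a modelling assumption, not an empirical claim:
  passing recovery tests shows the pipeline finds planted central
  modules, not that real disease genes are central.
* **Edge table**: rows carry UniProt-style accessions with an alias map
  back to symbols; 5% of rows get an accession absent from the alias map
  (testing the drop-and-count policy), a 10% admixture of foreign-taxon
  rows, plus a few duplicate rows and self-loops. Every contamination
  count is recorded as ground truth so the cleaning steps can be checked
  exactly.
* **Candidates**: 768 symbols — 456 network members (68 planted module
  genes ≈ 15%, the rest background network genes) and 312 non-coding
  style decoys that cannot map, mirroring a CNV catalogue where only
  protein-coding entries land in the network.
* **Pathways**: 20 random sets of 10–60 genes plus one planted pathway
  whose members are drawn from the mapped candidate list at a rate
  giving enrichment ratio ≈ the configured fold (default 10); at fold 1
  it is a null pathway. The universe is the 2,000 interactome genes plus
  4,000 universe-only symbols, so enrichment folds up to ~13 are
  representable.
* **Expression**: per-gene log-normal baseline (log2 TPM ~ Normal(3, 1.5)
  gene means, unit within-gene noise); block genes mix in a shared latent
  regional profile with weight √r, giving pairwise correlation ≈ r
  (default 0.8 over 13 regions).

Everything is a pure function of the spec and its RNG seed; two runs
with the same seed produce byte-identical files.

What the fixtures do **not** emulate: realistic interactome density or
motif structure, correlated study bias between interaction and pathway
databases, gene-length or region-size effects in CNV lists, or
measurement noise in expression. Tests passing on fixtures demonstrate
algorithmic correctness and calibration, not biological validity.

## Numerical and calibration choices

* Node and edge iteration is lexicographic wherever results could depend
  on order; all randomized procedures take explicit seeds.
* The Monte-Carlo validation fixture uses a 2,000-gene universe, a
  400-gene category and 932-gene draws, so the null coverage is
  46.6% ± ~2.2% while the observed coverage is placed at 96.5% — a
  desk-scale replica of the enrichment contrast the validation must
  resolve; the resulting t-statistic is astronomic and the p-value
  underflows well below 2.2e−16.
* The null-ORA calibration experiment uses reference 5,000 / query 500 /
  pathway 250 so that the discrete hypergeometric test's achieved size
  (~0.04) sits close to the nominal 0.05; with coarser parameters the
  test is conservative by discreteness, which would say nothing about
  the implementation.
* Default problem sizes (2,000-gene interactome, ~1,700-node network,
  1,000 Monte-Carlo draws, 200 calibration simulations) keep the full
  test suite and the acceptance script to a few seconds each while
  leaving every statistical contrast far from marginal.

## Known limitations

* The betweenness implementation is exact; for interactomes of 10⁴–10⁵
  nodes it still runs (minutes), but no sampled approximation is
  provided.
* ORA inherits pathway-database redundancy and ascertainment bias; the
  random-ORA control addresses list-composition bias only.
* The t-test p-value of the Monte-Carlo validation treats the null draws
  as a sample against a fixed observation; at extreme separations it is
  a headline number, and the empirical percentile is the honest bound.
* Interval-to-gene mapping for CNVs, ACMG classification, and live
  database queries are out of scope: the toolkit consumes files.
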