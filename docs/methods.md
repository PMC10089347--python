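# Methods

This note documents the models implemented in `ptmnet`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used at edge cases.

## Ratio computation

For a treated sample *t* of cell line *L*, a site's control baseline is
the arithmetic mean of the finite values in *L*'s vehicle-control
replicates. Fold change is `t/c` for increases and `-(c/t)` for
decreases; the magnitude is capped at 100 before taking log2. The stored
value therefore equals `clamp(log2(t/c), ±log2 100)` — a signed quantity
symmetric around zero, so the conventional 2.25-fold drug-effect cutoff
becomes ±1.17 on the log2 scale (`log2 2.25 = 1.1699…`; the rounded 1.17
is the default, the exact value can be passed instead).

Conventions at degenerate inputs: a zero or missing control mean, or a
missing treated value, leaves the ratio missing (never ±∞), with a
logged count. Control aggregation uses the arithmetic mean; this is a
configurable choice — the median is equally defensible and can be
swapped in by computing ratios manually.

## Dissimilarities and clustering

Three dissimilarities are computed over sites retained in ≥ 2 samples:

* **Euclidean**, pairwise-complete, scaled by `m/n_shared` (the R `dist`
  convention) so sparser pairs are not artificially close;
* **Spearman dissimilarity** `(1 − ρ)/2 ∈ [0, 1]`, pairwise-complete;
* **SED** `= sqrt(E_norm · spearman_dis)` with `E_norm` the Euclidean
  matrix divided by its finite maximum. The geometric mean combines
  response magnitude (Euclidean) with rank shape (Spearman)
  symmetrically in [0, 1]. The exact hybrid formula is an open design
  point; this definition is documented here and isolated in
  `dissimilarity_matrices` so it can be swapped.

Pairs sharing fewer than `min_overlap = 3` samples are set to the matrix
maximum: with < 3 shared points a correlation is meaningless, and
"unknown" should look maximally distant, not close. For the same reason
a co-cluster edge whose correlation is undefined keeps weight 0.

Each dissimilarity is embedded in 3-D with Barnes–Hut t-SNE
(`metric="precomputed"`, random init, per-metric seed recorded in the
run manifest). Perplexity defaults to 30, appropriate for data sets with
thousands of PTMs; it must be below (n−1)/3, and for the ~150-site
synthetic quick-start the packaged configs use 20 — at 30 the embedding
of a small data set can collapse distinct modules.

Clusters are cut from the Euclidean minimum spanning tree of each
embedding: edges longer than mean + `cut_sigma`·SD (default 1.0) are
removed and connected components become clusters. An all-zero distance
set yields a single cluster (coincident points stay connected; the MST
is built on an ε-shifted sparse matrix because the csgraph convention
treats exact zeros as missing edges). The final partition is the common
refinement of the three embedding partitions — two PTMs co-cluster only
if they co-cluster under all three metrics. Refinement means the final
clustering can only get finer, never coarser, than any single embedding.

## CCCN and protein collapse

Within each final cluster all PTM pairs are joined (clique edges)
weighted by pairwise-complete Spearman ρ. Separately, for every protein,
pairs of *different* PTM types with ρ < −0.5 are joined regardless of
cluster membership; these capture reciprocally antagonistic regulation
(e.g. acetylation vs ubiquitination of the same lysine). The negative
edges are added for all qualifying pairs, co-clustered or not; pairs
that are both co-clustered and strongly negative keep their co-cluster
edge and gain a boolean marker.

Protein-level collapse sums member-PTM log2 ratios into per-sample node
values (missing treated as 0 by default — the alternative of ignoring
missing values is a flag) and sums co-cluster edge weights between the
PTMs of each gene pair. Genes observed in fewer than 2 samples are
dropped. Ambiguous PTMs are attributed to their primary (first-listed)
gene for the collapse, while the CFN filter and CPE scoring credit every
candidate gene.

## CFN

PPI edge lists are merged with provenance union; physical edges are
canonically ordered, kinase→substrate edges stay directed, duplicate
rows take the maximum weight. The filter retains an edge iff some PTM of
one endpoint shares a final cluster with some PTM of the other — the
most permissive reading of "proteins with co-clustered modifications",
and monotone: merging clusters can only add CFN edges. The filter
applies to all edge types, including kinase–substrate edges.

## PCN scoring

Cluster Pathway Evidence divides each protein's in-cluster PTM count by
(number of pathways containing the protein × cluster size), so
promiscuous genes and giant clusters are discounted; ambiguous PTMs
contribute `1/|ambiguity group|` to each candidate. The pathway count in
the denominator is taken over the **full loaded collection**, not only
the pathways retained as PCN nodes — the discount should reflect a
gene's true promiscuity, which does not change when a pathway lacks
observed PTMs. Pathways with no PTM-bearing protein are dropped from the
node set. Raw pair weights sum CPE over clusters where **both** pathways
have nonzero evidence and are normalized by the global maximum over all
pairs in the run; the normalization is therefore run-relative, and
weights from different runs are not comparable.

Pathway GO similarity removes the gene intersection from both sets, then
averages the top-N gene-pair Otsuka–Ochiai similarities over all cross
pairs, reusing genes (N = 30 by default; all pairs if fewer exist). A
greedy one-to-one matching variant is available behind a flag. GO term
sets are used flat — no propagation through the ontology graph, and no
information-content weighting; that is a deliberate scope boundary.

Filtering of the PCN edge table combines the given bounds with AND;
`jaccard_max = 0` selects the zero-overlap pairs that are the main
object of crosstalk analysis.

## Downstream analyses

* **Cluster enrichment**: one-sided Fisher exact test (over-representation
  only) on the 2×2 affected/unaffected × in/out-of-cluster table, testing
  only clusters with ≥ 3 affected sites, BH correction across tested
  clusters, α = 0.05.
* **Composite shortest paths**: *all* tied shortest paths per cross
  pair, unweighted by default (a correlation-weighted option exists);
  unreachable pairs are counted, not fatal.
* **Mutual friends**: nodes outside both query sets adjacent to ≥ 1
  member of each; set members never qualify.
* **k-cores**: self loops and duplicate edges removed first, then
  standard iterative peeling; `core_overlap` cross-tabulates two core
  assignments and extracts the genes in designated high-core ranges of
  both networks.
* **Threshold matrices**: entries in {−1, 0, +1} from group medians at
  ±1.17; all-missing entries are 0; rows ordered by descending row sum
  with lexicographic tie-break for determinism.

## The synthetic world

`SimulationConfig` defaults describe a small but realistic experiment:
60 proteins in 6 co-regulated modules, 1–4 PTMs each (three PTM types),
five cell lines × two TKIs × two replicates plus two vehicle controls
per line (20 treatment:control ratio columns — the scale of a real
multi-cell-line TKI panel), mean module response of 3.0 log2 units
against 0.5 log2 units of replicate noise, and 15% missing values
(completely at random by default; an intensity-dependent option drops
low-abundance measurements preferentially).

Each module responds in its own random subset of drug × cell-line
conditions (Bernoulli 0.6 per condition) — its condition *barcode* —
with a fixed response sign per module; in responsive conditions the
latent log2 response is Normal(±effect_size, 1), elsewhere Normal(0, 1).
The barcode model reflects how inhibitor response tracks the driver
kinase of each cell line, and it is what makes distinct modules
statistically distinguishable: with a single always-on response level,
two same-sign modules differ only by Normal(0, 2) per condition
regardless of effect size, and no clustering method can separate them.
Barcodes are resampled until every pair differs in ≥ 3 conditions, so
the planted partition is identifiable by construction.

Pathways and annotations live in a continuous "functional
neighborhood": genes sit on a unit circle, each background pathway draws
~80% of its members near a random center (σ = 0.06), and each gene draws
GO terms (6 per gene, bias 0.85) from a window of the term list centered
at its own position. Nearby pathways therefore share both genes and
annotation structure in a graded way. Planted crosstalk pairs split the
genes of two whole modules between two disjoint gene sets, giving the
pair shared responsive clusters with zero gene overlap. The PPI graph
connects within-module gene pairs with probability 0.4 and background
pairs with probability 0.05.

`module_layout` selects whether response modules align with the
functional gene ordering (`"blocks"`, default — pathway-coherent
clusters, the regime for crosstalk detection and CFN retention) or cut
across it (`"interleaved"` — the regime mirroring real collections,
where cluster weight is nearly independent of gene overlap while GO
similarity tracks it).

What a green test establishes: that the pipeline recovers planted
co-response structure, ranks planted crosstalk above coincidental
zero-overlap pairs, and preferentially retains module-internal PPI
edges, all under MS-like sparsity. What it does not establish: behavior
under batch effects, intensity-dependent ratio compression,
peptide-level quantification error, incomplete/biased PPI databases, or
pathway collections three orders of magnitude larger — the generator
does not model those.

## Reproducibility

Every run writes a manifest (config snapshot, SHA-256 input checksums,
per-metric t-SNE seeds, per-stage counters). All randomness flows
through explicit seeds; identical config + inputs reproduce every output
byte-for-byte (scikit-learn's t-SNE is deterministic for a fixed
`random_state` within a library version, so bit-level reproducibility is
per-environment).

## Known limitations

* t-SNE + MST cluster boundaries are seed-sensitive for borderline
  points; the partition intersection mitigates but does not remove this.
  Cluster-level downstream claims should be read accordingly.
* The PTM cluster weight normalization is run-relative (global maximum).
* Gene identity is bare uppercase symbols; no identifier mapping beyond
  an optional static alias table.
* GO similarity ignores the ontology hierarchy by design.
* `pathway_go_similarity` enumerates all cross pairs; for very large
  pathway collections the PCN build is O(pairs × genes²) and is the slow
  stage.
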