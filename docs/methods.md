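# Methods

This note documents the statistical model behind `netnoise`, the design
choices made where the procedure was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Problem and model

Common risk variants for highly polygenic disorders have effects too
small for single-SNP genome-wide significance; much of the signal sits
below conventional thresholds, inside the statistical "noise" band.  The
premise of the method is that genes carrying true sub-threshold signal
are functionally related, and that functional relatedness is visible as
physical proximity on a protein–protein interaction (PPI) network:
proteins of true risk genes interact directly more often, are isolated
less often, and coalesce into a larger connected component than random
protein sets of the same size, while pure noise scatters.

The pipeline is:

1. **Gene scoring.**  Every SNP is assigned to each gene whose body
   ±`window_bp` (default 10 kb, symmetric, strand-ignored) covers its
   position; a SNP inside two overlapping windows counts for both
   genes.  A gene's raw score is its best (minimum) SNP p-value.
2. **Confounder correction.**  The best-SNP minimum is biased by gene
   size and SNP density.  We regress y = −log10(best p) on gene-level
   covariates — gene size (kb), SNP count, SNPs/kb, plus any
   user-supplied columns — by forward-stepwise OLS (a covariate enters
   while the AIC improves), and convert the residuals r to corrected
   p-values by the empirical rank transform
   `corrected_p = rank(−r) / (N + 1)`.
3. **Projection.**  Genes with corrected −log10 p ≥ c are mapped to
   their proteins (union over all mapped proteins) on the network.
4. **Coherence testing.**  At each cutoff c in a grid (default 0.5–5.0
   step 0.5), three metrics of the selected protein set are compared
   with `n_perm` (default 1000) equal-size uniform random protein sets:
   % of proteins with ≥1 within-set edge, % isolated, and largest
   connected component (LCC) size.  Empirical p = (1 + r)/(n_perm + 1)
   with ties counted as extreme.
5. **LCC extraction and benchmarking.**  At a working cutoff (default
   −log10 p = 1, i.e. gene-wise P < 0.1; `auto` picks the smallest
   scanned cutoff with all three metrics significant at α = 0.05) the
   LCC gene set is compared against a candidate list (precision/recall)
   and against two baselines: all genes at the cutoff, and the
   equally-sized top-ranked gene list.
6. **Cross-dataset overlap and specificity.**  Two datasets are compared
   by Jaccard index at SNP, gene and LCC level (per-dataset top-N lists
   with N = that dataset's LCC gene count).  Primary-LCC proteins are
   ranked by a score starting at 0.5, +0.5 if present in a replication
   dataset's LCC, −0.5/K for each of K unrelated-disease LCCs containing
   the protein (K = 6 classically), computed in exact rational
   arithmetic so the lattice {0, 1/12, …, 1} is hit exactly.

## Design choices

**Rank-based correction ("MAGENTA-like").**  The reference gene-scoring
tool regresses out additional LD-derived covariates (independent SNPs,
recombination hotspots, LD units/kb) that require external LD maps; we
accept such columns as optional user input but do not compute them.
The residual-to-p transform is a deliberate choice: a parametric
residual p-value would depend on the error distribution of the
regression, whereas the rank transform preserves the residual ordering
exactly, guarantees corrected p ∈ (0,1) with no ties, and is uniform by
construction under the null.  Its cost is that exactly a fraction
10^(−c) of scored genes passes any cutoff c, signal or not; selection
power comes from *which* genes occupy the top ranks.

**Connectivity semantics.**  "Reachable from each other" is evaluated on
the subgraph induced by the selected proteins: unselected proteins never
bridge components.  This matches the isolated-node definition (no edge
to any other *selected* protein) and makes the three metrics internally
consistent.

**Direct-interaction metric.**  The fraction of selected proteins with
at least one within-set partner is the primary definition, so
%direct + %isolated = 100 identically.  Because "proteins directly
interacting" can also be read pairwise, the within-set edge density
(edges / C(n,2)) is computed and tested alongside in every scan.

**Null model.**  Uniform sampling of equal-size node sets from the full
network is the default.  A degree-matched mode (sampling within degree
deciles to match the observed set's profile) is available as a
robustness check for degree-driven selections.  The empirical-p
estimator (1+r)/(n+1) never returns 0; its floor at the default 1000
permutations is 1/1001 ≈ 0.001.

**Determinism.**  All randomness flows through one seeded
`numpy.random.Generator`; ties in ranking and ordering are broken by
(value, id) everywhere, so a fixed config + seed reproduces every output
byte-for-byte (`run_all` records config, input checksums, seed and
stage counts in `manifest.json`).

## The synthetic-data generator

`simulate` produces studies with the structure the analysis assumes:
an Erdős–Rényi background network (Barabási–Albert optional) at the mean
degree of the large compiled human interactome it stands in for
(2·58365/12372 ≈ 9.4); a planted connected module of `module_size`
proteins whose internal edge probability is `module_edge_boost` × the
background density (capped at 1); non-overlapping gene bodies laid out
with intergenic gaps wider than twice the assignment window (so SNP→gene
assignment is exactly checkable), ~10 SNPs per gene plus intergenic
SNPs placed outside every window; a 1:1 gene↔protein map; SNP p-values
Uniform(0,1) off the module and Beta(b,1) (CDF x^b) inside
signal-carrying module genes; and a candidate list drawing a controlled
fraction from the module.

Defaults are desk-scale study conditions chosen once: 2000 proteins,
3000 genes, module 60, boost 5, signal in 80% of module genes with
b = 0.2, candidate list of 60 with 50% module overlap.  Because the
module's internal ER draw at realistic sparsity is rarely connected by
itself, the generator retries the internal draw a bounded number of
times and then joins remaining module components with random
inter-component edges; the planted module is therefore connected by
construction, at the cost of an effective internal density somewhat
above `boost × p` at sparse settings.

What the generator does **not** emulate: LD between SNPs (p-values are
independent), heavy-tailed PPI degree distributions (unless the BA model
is chosen), annotation errors, and many-to-many gene↔protein maps.
Passing tests on these data show the pipeline's statistical machinery is
correct and calibrated; they do not certify performance on real
cohorts, where LD, network ascertainment bias and candidate-list
curation all matter.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive; BED input is converted at the
  boundary.  Chromosome names are compared after stripping `chr`.
* p-values must lie in (0,1]; rows with p ≤ 0, p > 1 or missing values
  are dropped and counted in the load report.
* Self-loops and duplicate edges are removed on network load (metrics
  are defined on distinct partners).
* Empty selections: `topology_metrics` returns all-zero metrics; a
  cutoff scan truncates at the first cutoff with an empty protein set.
* The stepwise regression refuses fewer than 10 genes; constant or
  non-finite covariate columns are dropped with a warning, and a
  candidate covariate that is collinear with already-entered ones is
  skipped.
* Specificity scores are `fractions.Fraction` internally; TSV output
  rounds to 4 decimals.

## Problem sizes used in the test suite

The statistical acceptance tests run the full pipeline at the default
study conditions: 200 null-calibration replicates (no signal,
200 permutations each) for the uniformity of empirical p-values;
50 planted-module replicates (1000 permutations) for recovery; 50
replicates for the precision/recall pattern; 200 random instances
(n ≤ 50) for oracle agreement of component extraction and metrics.

## Known limitations

* Planted-module detection at the default desk scale operates near the
  percolation threshold of the induced subgraph, where the null LCC has
  a long upper tail; single-replicate LCC significance can therefore be
  marginal (empirical p ~0.01–0.03) in a minority of runs even with a
  strongly signalled module.  At full interactome scale the regime is
  more favorable.
* The correction regresses only size/density covariates by default; LD
  structure must be supplied by the user as extra covariate columns to
  be removed.
* Candidate matching is exact (case-normalized) symbol equality; alias
  resolution is the user's responsibility.
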