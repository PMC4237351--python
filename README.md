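# netnoise

Network-based recovery of disease signal hidden in GWAS statistical
noise.

Genome-wide association studies of highly polygenic disorders leave most
true risk loci below genome-wide significance.  `netnoise` implements a
network strategy for mining that sub-threshold band: it computes
confounder-corrected gene-wise p-values from per-SNP association
results, superimposes genes selected at permissive cutoffs onto a
protein–protein interaction (PPI) network, and asks whether the selected
proteins are *functionally coherent* — interacting directly, rarely
isolated, and connected into a large component — beyond what equal-size
random protein sets show.  The largest connected component (LCC) then
serves as a prioritized gene set that can be benchmarked against known
candidates, compared across cohorts, and ranked for
reproducibility/specificity against unrelated-disease networks.

It is intended for statistical geneticists and systems biologists who
have per-SNP association tables (e.g. PLINK output), a gene annotation,
a PPI edge list and a gene↔protein id map.

## Model

For gene g with assigned SNPs S(g) (within ±10 kb of the gene body by
default), the raw score is p_g = min_{s∈S(g)} p_s.  Because min-p is
confounded by gene size and SNP density, y_g = −log10 p_g is regressed
on gene-level covariates by forward-stepwise OLS (AIC), and residuals
r_g are mapped to corrected p-values by the rank transform
corrected_p_g = rank(−r_g)/(N+1).

At cutoff c, the selected protein set V_c (genes with
−log10 corrected_p ≥ c, mapped to network nodes) is scored on the
induced subgraph by

* % directly interacting: 100·|{v : deg_{V_c}(v) ≥ 1}|/|V_c|,
* % isolated: the complement,
* LCC size: the largest component of the induced subgraph,

each tested against n_perm = 1000 equal-size uniform random node sets
with empirical p = (1 + r)/(n_perm + 1) (floor 1/1001).  Precision and
recall of a selection A against candidates C are |A∩C|/|A| and
|A∩C|/|C|; cross-dataset overlap is the Jaccard index |A∩B|/|A∪B|; a
primary-LCC protein's specificity score is
0.5 + 0.5·[in replication LCC] − (0.5/K)·(# of K unrelated-disease LCCs
containing it) ∈ [0, 1].

## Worked example

A synthetic study with a planted 60-protein disease module (five-fold
internal edge enrichment; 80% of module genes carry Beta(0.2, 1)
sub-threshold signal) on a 2000-protein network:

```python
import netnoise as nn

ds = nn.generate_dataset(nn.SyntheticConfig(seed=7))
model = nn.NetworkGwas.from_synthetic(ds)
res = model.fit(n_perm=1000, seed=3)
print(res.summary())
```

```
Network-based GWAS coherence analysis
================================================================
dataset: synthetic
SNPs: 50013   genes annotated: 3000   genes scored: 3000
network: 2000 proteins, 9510 interactions
assignment window: +/-10000 bp   permutations: 1000   seed: 3

Coherence scan (observed vs. equal-size random protein sets)
----------------------------------------------------------------
cutoff  n_sel  %direct   %isol   LCC  p_direct   p_isol    p_lcc
  0.50    651     96.0     4.0   623    0.2797   0.2797   0.1728
  1.00    220     73.6    26.4   109    0.0100   0.0100   0.0020
  1.50     76     59.2    40.8    27    0.0010   0.0010   0.0010
  2.00     30     83.3    16.7     8    0.0010   0.0010   0.0010
  2.50      9     22.2    77.8     2    0.1528   0.1528   0.1528
  3.00      3      0.0   100.0     1    1.0000   1.0000   1.0000
----------------------------------------------------------------
LCC extracted at -log10 P = 1: 109 proteins / 109 genes (77 components, 220 selected proteins)

Candidate benchmark
----------------------------------------------------------------
     selection      n  hits  precision%  recall%
     lcc_genes    109    21       19.27    35.00
     top_genes    109    25       22.94    41.67
 all_at_cutoff    300    28        9.33    46.67
```

Reading the output: at gene-wise P < 0.1 (−log10 P = 1) the 220 selected
proteins form a 109-protein LCC whose size has empirical p = 0.002
against 1000 random sets — the sub-threshold band is functionally
coherent, not noise.  The LCC gene set is roughly twice as precise
against the (half-module-overlapping) candidate list as the full
cutoff selection (19.3% vs 9.3%), at the expected cost in recall
(35% vs 46.7%), since LCC genes are a subset of the cutoff selection.
At stricter cutoffs the selection thins until coherence is undetectable.

The same workflow runs from files via the CLI:

```sh
netnoise simulate --out simdir --seed 7
netnoise run --config run.yaml          # score -> scan -> LCC -> evaluate
netnoise specificity --primary-lcc a.txt --replication-lcc b.txt \
    --unrelated d1.txt ... --unrelated d6.txt --out scores.tsv
```

`run` writes `gene_scores.tsv`, `coherence_scan.tsv`, `components.tsv`,
`lcc_genes.txt`, `evaluation.tsv`, a plain-text summary and a
`manifest.json` (config, input checksums, seed, stage counts) that makes
the run bit-for-bit reproducible.

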