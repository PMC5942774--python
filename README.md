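# cibkit

Codon-usage-bias analysis for comparative bacterial genomics, built around
the **codon information bias (CIB)** statistic. The motivating use case is
comparing groups of genes — e.g. genes of copper-bioleaching acidophilic
bacteria versus reference gene sets, or conserved versus strain-unique
genes — by how strongly each gene concentrates its synonymous codon usage.

## The statistic

For a coding sequence, let p(a) be the relative frequency of amino acid *a*
among its codons, n(a) the number of sense codons in *a*'s synonymous
family, and H_a the Shannon entropy of codon usage within that family.
CIB is the amino-acid-weighted Kullback–Leibler divergence of the observed
within-family codon usage from uniform usage, rescaled to [0, 1]:

```
CIB = Σ_a p(a) · (log n(a) − H_a)  /  Σ_a p(a) · log n(a)
```

CIB = 0 iff every synonymous family is used uniformly (no bias); CIB = 1
iff every amino acid present is encoded by a single codon (maximal bias).
Genes containing only non-degenerate amino acids (Met/Trp) have an
undefined CIB and are flagged rather than dropped silently.

Around the statistic the package provides:

- **codon counting** from CDS FASTA (genetic-code tables 1 and 11),
- a **two-stage group comparison**: two-sample Anderson–Darling test of
  distributional equality, then — only where a difference is detected —
  permutation tests for *stochastic dominance* in each direction
  (X is stochastically smaller than Y when their empirical CDFs do not
  cross; the statistic is the one-sided maximal CDF gap, with a
  Monte-Carlo p-value (1 + exceedances)/(1 + permutations)),
- **functional summaries**: COG-category assignment from tabular alignment
  hits (e-value ≤ 1e-5, identity ≥ 40%, optional 90% length fraction),
  ortholog-pair intersection and conserved/unique partitioning, mean CIB
  per category and per 500-nt gene-length bin,
- **strain clustering**: average-linkage hierarchical clustering of
  category-wise mean-CIB profiles under Pearson correlation distance,
- a **synthetic CDS generator** with a single bias knob β whose population
  CIB is known in closed form, used as ground truth throughout the tests.

## Worked example

Simulate two gene groups with weak (β = 0.1) and strong (β = 0.5)
synonymous bias, compute CIB, and compare them:

```
$ cat model.yaml
seed: 7
length_dist: [fixed, 300]
groups:
  - {name: low,  beta: 0.1, n_genes: 60, categories: [P, O, C]}
  - {name: high, beta: 0.5, n_genes: 60, categories: [P, O, C]}

$ cib simulate --config model.yaml --out-dir sim
group low: 60 genes, population CIB 0.0098
group high: 60 genes, population CIB 0.2188

$ cib compute --fasta sim/low.fasta --fasta sim/high.fasta --out-dir cib
wrote cib/low.cib.tsv (60 genes)
wrote cib/high.cib.tsv (60 genes)

$ cib compare --cib-x cib/low.cib.tsv --cib-y cib/high.cib.tsv \
      --categories sim/categories.tsv --n-perm 2000 --seed 3 --out compare.tsv
wrote compare.tsv (3 categories)

$ column -t compare.tsv | tail -4
group_x  group_y   category  n_x  n_y  ad_statistic  ad_p      dom_xy_p  dom_yx_p  verdict
low.cib  high.cib  C         16   24   15.222129     0.001000  0.000500  1.000000  x_stochastically_smaller
low.cib  high.cib  O         26   17   16.315523     0.001000  0.000500  1.000000  x_stochastically_smaller
low.cib  high.cib  P         18   19   14.415288     0.001000  0.000500  1.000000  x_stochastically_smaller
```

Reading the output: in every COG category the Anderson–Darling stage
rejects equality (p = 0.001, the floor of the asymptotic interpolation),
and the dominance stage finds the low-β group stochastically smaller
(dom_xy_p = 0.0005 = 1/2001, the Monte-Carlo floor at 2000 permutations)
with no evidence in the opposite direction — exactly the ordering the
generating β values imply.

The package also ships a small published table of per-gene CIB values for
copper-resistance and oxidative-stress homolog pairs in biomining strains
(`cibkit.examples`); averaging its columns gives block means 0.186 vs
0.232 (copper) and 0.236 vs 0.264 (ROS), the consortium strains showing
the lower bias.

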