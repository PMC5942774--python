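# Methods

## The CIB statistic

For one coding sequence, every complete in-frame codon is counted over the
61 sense codons of the genetic code (tables 1 and 11 are supported; their
sense-codon degeneracy is identical, so CIB does not depend on the choice).
With p(a) the amino-acid relative frequency among counted codons, n(a) the
synonymous-family size and q(c|a) the within-family codon frequencies,

    numerator   = Σ_a p(a) · (log n(a) − H_a),   H_a = −Σ_c q(c|a) log q(c|a)
    denominator = Σ_a p(a) · log n(a)
    CIB         = numerator / denominator ∈ [0, 1].

log n(a) − H_a is the Kullback–Leibler divergence of q(·|a) from the
uniform distribution on the family, so the numerator is the
composition-weighted KL divergence from unbiased synonymous usage and the
denominator is its maximum given the amino-acid composition. Consequences
used as exact test oracles: CIB = 0 iff every family is used uniformly;
CIB = 1 iff each amino acid present uses a single codon; the value is
invariant to scaling all counts and to the logarithm base.

Numerical conventions: natural log internally; 0·log 0 = 0; amino acids
absent from the gene and single-codon families (Met, Trp) contribute
nothing; no pseudocounts, so unused codons enter H_a as true zeros —
anything else would break the single-codon maximum. A gene whose counted
codons are all Met/Trp has denominator 0; its CIB is NaN with an
`undefined-cib` flag, and downstream statistics drop flagged rows with a
logged count rather than raising.

Counting contracts: the terminal stop codon is excluded by default;
internal stops are flagged but do not abort (draft genomes contain
pseudogenes); codons with ambiguity characters are skipped and flagged,
not imputed; a trailing partial codon is dropped and flagged; the frame is
taken as given (CDS input, no ORF detection); counting is case-insensitive
and accepts RNA (U→T).

## Two-stage group comparison

Stage one tests H0 "same distribution" with the two-sample
Anderson–Darling test (Scholz–Stephens k-sample statistic, k = 2), chosen
over Kolmogorov–Smirnov for its tail sensitivity. The ties-adjusted
midrank variant is the default since CIB samples contain ties; the
continuous variant is available and is the one with the clean closed-form
double sum used in the worked example. The reported raw statistic is
computed in-package; the standardization and p-value (interpolation of the
standardized statistic against the asymptotic points, clipped to
[0.001, 0.25] outside the grid, or a label-permutation p on request) come
from scipy's implementation of the same Scholz–Stephens procedure.

Stage two runs only where stage one rejects at level α (default 0.01). For
direction "x below y" the statistic is the one-sided maximal empirical-CDF
gap D = max_t (F̂_x(t) − F̂_y(t)), clipped at 0 and evaluated at the pooled
distinct values. D is the minimal statistic whose null (equality) and
alternative (the CDFs do not cross, one lying above) match the stochastic
dominance being asserted. The null is simulated by relabeling the pooled
sample: when the pooled size is ≤ 12, all C(N, n_x) splits are enumerated
and the p-value is exact; otherwise p = (1 + #{D* ≥ D_obs})/(1 + B), which
is never 0 and has resolution 1/(B+1) (B = 10,000 by default). Both tests
are rank-based, hence invariant under strictly increasing transforms.

Verdict per category: `same` when stage one does not reject; otherwise
`x_stochastically_smaller` (resp. y) when exactly that direction's
dominance test is significant at α, and `different_unordered` when both or
neither are — the latter covers crossing CDFs, e.g. equal-median groups
with different spread. Per-category p-values are reported uncorrected, as
is conventional when each category is read as its own comparison; a Holm
step-down option exists but is off by default. Categories with fewer than
2 defined values in either group are skipped with a logged reason. All
permutation randomness derives from one integer seed, with per-category
substreams spawned deterministically so results do not depend on category
order.

## Functional grouping and summaries

COG assignment consumes standard 12-column tabular alignment hits (or the
14-column variant with query/subject lengths) and keeps hits with
e-value ≤ 1e-5 and identity ≥ 40%; in metagenome mode a query must
additionally cover ≥ 90% of the hit length, which requires the 14-column
input. Categories are unioned per gene across surviving hits, and a gene
with a multi-letter assignment (e.g. "O,C") contributes its CIB once to
every letter — the published summary tables display multi-letter entries
but no counting rule, so both this and a first-letter-only mode exist,
with per-letter counting the default.

Ortholog handling: only pairs called by both upstream tools (their lists
are consumed as two-column TSV) are kept, order-normalized; genes in any
surviving pair are "conserved", the rest "unique" — no reciprocal-best
re-filtering, which is the upstream tools' job. Group × category mean
matrices pool genes across a group by default; averaging per-species means
instead is available behind a flag since "average over all the species of
a group" is ambiguous between the two. Empty cells are NaN, never 0.
Length bins are half-open intervals (ℓ−500, ℓ] with ℓ a multiple of the
bin width (default 500 nt): a 500-nt gene falls in bin 500, a 501-nt gene
in bin 1000.

## Strain clustering

Strains are clustered by their category-wise mean-CIB profiles using
unweighted average linkage on Pearson correlation distance 1 − r
(range [0, 2]). Missing categories are handled by pairwise deletion inside
each distance (≥ 3 complete pairs required; a constant profile makes the
distance undefined and raises, naming the strain pair). Rows are not
centered or normalized before clustering — correlation distance is already
shift- and scale-invariant per pair, and whether the original tooling
normalized additionally is unknowable, so the minimal choice wins. Merge
ties break toward the lexicographically smallest cluster-name pair, making
the dendrogram independent of input row order. Newick export assigns
ultrametric branch lengths (merge height / 2). Heights are cross-checked
against scipy's average-linkage implementation in the tests.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
per-gene codon counts over labeled gene groups — with ground truth known
in closed form. Amino acids are i.i.d. from a composition p(a) (default
uniform over the 20; a GC-rich-like skewed preset is provided), and codons
are drawn from

    q(c|a) = β·1[c = preferred(a)] + (1 − β)/n(a),   β ∈ [0, 1],

with preferred(a) the alphabetically first codon of each family. The
mixture form was chosen over e.g. Dirichlet draws because it gives a
closed-form population CIB that hits both extremal characterizations
exactly (0 at β = 0, 1 at β = 1) and is strictly increasing in β whenever
a degenerate amino acid is present. Gene lengths come from a configurable
model — fixed, uniform, or the default rounded log-normal with median 300
codons and σ = 0.45, floored at 30 codons, mimicking a typical bacterial
CDS length distribution. A TAA stop is appended so the files are valid CDS
for the counting contract. One seeded generator drives each simulation
call; identical seeds give byte-identical FASTA.

What the generator does *not* emulate: operon structure, GC gradients,
tRNA-adaptation-driven preference hierarchies, or correlated codon usage
along a gene. Passing tests therefore demonstrate that the pipeline
recovers known bias structure under the model's i.i.d. assumptions, not
that any particular biological claim about real genomes is reproduced.

Finite-sample behavior: the plug-in entropy estimator is biased downward,
so short genes have inflated empirical CIB even at β = 0 — the simulation
studies verify both this length dependence and the convergence of the
empirical mean to the population CIB (within 0.02 at 10⁴ codons in the
acceptance run).

## Problem sizes in the validation runs

The simulation studies use sizes chosen to make their Monte-Carlo
tolerances meaningful while keeping the whole validation quick on a
laptop: 1,000 random count tables for the brute-force cross-check (1e-12
agreement), 200 replicates for type-I error (three binomial standard
errors around α = 0.05), 10⁵ permutations for exhaustive/Monte-Carlo
agreement (three MC standard errors), 20 pipeline runs of 200 genes per
group for the end-to-end ordering check, and 10 strains from two templates
for clustering recovery.

## Known limitations

- Only genetic-code tables 1 and 11; organisms using other codes are out
  of scope.
- The dominance verdict treats the two directional tests independently at
  the same α; no joint calibration is attempted.
- The asymptotic AD p-value is clipped below at 0.001; analyses needing
  smaller exact p-values should use the permutation method.
- CIB is length-biased for short genes (entropy plug-in bias); compare
  groups with similar length distributions or inspect the length-bin
  summaries.
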