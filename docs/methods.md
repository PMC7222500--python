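# Methods

This note documents the models, numerical choices and synthetic-data
design behind `cpscreen`, and what the tests do and do not establish.

## Ranked signatures

Expression matrices (genes × samples, log2 scale) are quantile-normalized
(each column forced onto the distribution of across-column sorted-value
means; ties resolved by stable sort order), restricted to a gene universe
via a source→target mapping table (first mapping wins on duplicates, with
a logged warning), and scored per gene with a pooled-variance two-sample
*t* for the test-vs-reference contrast:

t_g = (x̄₁ − x̄₂) / (s_p · sqrt(1/n₁ + 1/n₂)),

with the pooled SD floored at the 1st percentile of gene-wise pooled SDs
(plus an absolute floor of 1e-8). The floor plays the role of variance
moderation at a fraction of its complexity: it stops near-zero-variance
genes from producing enormous *t* values, and it makes a gene with zero
variance *and* zero mean difference score exactly 0 rather than NaN. A
plain mean-difference statistic is available (`statistic="diff"`) because
the choice of ranking statistic is a genuinely open design point; the two
give very similar rankings on the synthetic data. Ties in score are
broken lexicographically by gene id so the ranking, and everything
downstream of it, is deterministic. Positive score ⇔ higher in the test
(juvenile / knockout) group.

Probe-level background correction is out of scope: inputs are assumed to
be positive, probe-summarized values, with log2 applied upstream.

## Chemical libraries

Interaction records are kept when the target type is `mRNA`, the
reference field is non-empty, and the action parses (prefix match on
`increases`/`decreases` before a `^` separator, the CTD export
convention); duplicates of (chemical, gene, action) collapse to one
record. Out-of-universe genes are removed *before* the minimum-size
filter (3 genes), and the filter applies to each dialect independently —
a chemical can be present in the composite library but absent from a
directional one. No maximum-size filter is applied; observed size ranges
are logged as data properties.

## GSEA engine

The enrichment score is the classic weighted KS running sum (weight
exponent 1 by default, 0 for the unweighted statistic). Two
implementations coexist deliberately: a direct cumulative-sum path used
for single sets (and returning the full running sum), and a vectorized
path that evaluates only the candidate extrema — the running-sum values
immediately after each hit (maxima) and immediately before each hit
(minima). The two are cross-checked against each other and against a
loop oracle in the tests. Exact |max| = |min| ties of the running sum
occur *generically* (they follow from the miss-step arithmetic, not from
score coincidences), so the tie rule — prefer the positive extremum —
carries a 1e-12 tolerance to keep the two paths and any reimplementation
in agreement under float jitter. If every hit weight is zero (an
all-zero-score set) the weights fall back to uniform.

The null is a gene-set permutation null: ES values of uniformly sampled
same-size sets. Phenotype permutation is not an option at n = 3 per
group, and the size-matched random-set null is precisely what gives the
FDR its set-size control. Chemicals with identical set sizes share one
null batch; each batch's RNG is seeded by (seed, set size), so results
do not depend on scoring order and regenerating one batch never shifts
another.

Per chemical: the nominal *P* is the add-one same-sign tail,
(1 + #{null same sign, at least as extreme}) / (1 + #{null same sign}),
so *P* is never 0 and never below 1/(n_perm + 1); NES divides ES by the
mean |null ES| of the same sign; the FDR *q* compares the same-sign tail
fraction of the pooled null NES (each batch's nulls normalized within
the batch, pooled once per chemical of that size so the null pool
mirrors the observed size distribution) with the same-sign tail fraction
of observed NES, clipped to [0, 1]. Sign pools are handled separately
throughout, the standard GSEA convention. An ES of exactly 0 gets
*P* = 1, NES = 0, *q* = 1.

Defaults: n_perm = 1000, screening thresholds *P* < 0.05 and FDR < 0.25
(an intentionally permissive discovery threshold), negative-score filter
for the directional screen.

## Bias tests and candidates

Binomial tests are exact and two-sided by the minimum-likelihood rule
(scipy's `binomtest`), which the tests verify against full enumeration.
The up-vs-down bias test defaults to the library-share null
p₀ = n_up/(n_up + n_down), with p₀ = 0.5 available, since which null the
original analysis used is not determinable; both are reported by the
pipeline. Overlap statistics report the sample cross-product odds ratio
a·d/(b·c) — not the conditional-MLE OR some tools print — with an
infinity flag when b·c = 0 < a·d, and a one-sided Fisher *P* computed as
the exact hypergeometric upper tail.

## CGEA

Level one tests every chemical up-set against every pathway set with a
one-sided Fisher test whose universe is the declared signature universe
(chemical sets are already restricted to it; pathway sets are
intersected with it first, and pathways left empty are dropped with a
log entry). Cell-wise *P* values are computed vectorized as
hypergeometric upper tails — mathematically identical to one-sided
Fisher, verified cell-by-cell against `scipy.stats.fisher_exact` in the
tests. BH correction is **global across the whole chemicals × pathways
matrix** (one correction per pathway library); a per-chemical scope is
available behind a flag. Binarization at P_adj < 0.05.

Level two, per pathway: with N chemicals, K candidates, and n chemicals
enriched for the pathway, the upper-tail hypergeometric
P(X ≥ x) for x enriched candidates, BH-corrected across pathways,
selected at P_adj < 0.05. A pathway with no enriched chemical gets
*P* = 1 and a flag. The BH step-up itself is implemented in the package
(sort, multiply by m/rank, enforce monotonicity downward, cap at 1) and
is checked against statsmodels on random vectors to < 1e-12.

## Clustering, exposure, microglia

Features are −log10 P_adj over the CGEA-selected pathways, with P_adj
floored at 1e-300 (underflow guard) and capped at 1 (non-enriched cells
are 0). Log base is immaterial to Ward clustering (a common rescaling);
base 10 is used for readability.

Ward linkage: scipy's `ward` on a condensed distance vector implements
the Ward.D2 recurrence. The default here is Ward.D — the same recurrence
applied to *unsquared* Euclidean distances, as in R's `hclust` — which
is obtained by feeding scipy the square roots of the distances: a
monotone transform of the merge heights that leaves the merge order, and
hence the k-cut partition, exactly Ward.D's. `linkage="ward_d2"`
switches to Ward.D2. The tree is cut at k = 2.

Cluster labels are semantic: "A" is the enrichment-sparse cluster (lower
mean feature value), with ties broken toward the larger cluster being A.
The exposure contrast reports the fold enrichment of medium/high-risk
chemicals in B vs. A and two exact binomial constructions of the same
contrast — the split of all medium/high chemicals across clusters
against p₀ = |B|/(|A|+|B|), and the same split against p₀ = 0.5 —
because the published description of this test is ambiguous; the first
construction reproduces the published *P* on the published counts. A
cluster with no annotated chemicals flags the result rather than
dividing by zero.

The microglia scan is a per-candidate one-sided Fisher test of the
up-set against the activated-microglia set over a configurable
background size (the signature universe by default; 15 071 genes in the
original analysis), BH-corrected across candidates, with the enriched
flag contrasted across clusters by another Fisher test.

## Synthetic study design

The generator emulates the screen's inputs at desk scale with planted
ground truth. Defaults: 2000 genes, 3 samples per group, 200 brake genes
shifted −2.0 (log2) in the test group of both contrasts with an
equal-sized decoy set shifted +2.0, within-group noise SD 0.5 around
gene baselines drawn from N(8, 1); 300 chemicals with 5–100 genes per
direction, 30 planted disruptors drawing 60% of their up-genes from the
brake pool; 250 pathways (sizes 10–60) with 15 planted (sizes 40–80, 80%
of members from the brake pool); a 72-gene microglia set; exposure
labels medium/high with probability 0.7 for planted cluster-B chemicals
and 0.35 (the sparse-cluster rate in the original data) otherwise. Each
artifact uses its own RNG stream (master seed + fixed offset), so
regenerating one artifact never shifts another, and output files are
byte-identical across runs at a fixed seed.

Two structural choices matter for recoverability and were corrected
during development of the generator itself:

- The brake pool splits into two **equal** disjoint subpools (100/100);
  cluster-B disruptors, the cluster-B planted pathways (60% of planted
  pathways) and the microglia set (70% of its members) draw from one
  subpool, cluster-A disruptors and pathways from the other. Equal pools
  keep per-pathway enrichment strength comparable between clusters, so
  cluster B is the enrichment-dense cluster by virtue of its larger
  pathway count — matching the semantic labeling rule.
- Planted disruptors draw set sizes from the **upper half** of the
  configured size range. A "planted" chemical with a five-gene set
  carries ~3 planted genes — no recoverable cluster signal exists even
  in principle — so the planted chemicals are defined as the ones with
  informative set sizes, mirroring the fact that the original candidate
  set consisted of chemicals with detectable signatures.

The generator also emits records the parser must drop (≥1% non-mRNA
target types, ≥1% empty-reference records) and an identity ortholog
mapping so the universe filter is exercised.

One pathway library is emitted rather than separate GO-BP-like and
ligand-like libraries: the two differ only in content, not mechanics,
and the CGEA code accepts any number of libraries.

What the synthetic data does **not** emulate: probe-level microarray
noise and batch effects, correlated gene-gene structure within pathways,
the long-tailed size distributions and chemical ontology of real CTD
data, and GO's hierarchical redundancy. Passing recovery tests therefore
demonstrates the correctness and calibration of the pipeline's
statistics on independent-gene data, not performance on real microarray
or CTD inputs.

## Problem sizes and determinism

The test suite and the acceptance script run the default study
(300 chemicals × 2000 genes, 1000 permutations) for recovery checks
— about 20 s per seed, three seeds — and a scaled-down study
(60 chemicals × 400 genes) for orchestration and determinism checks.
Type-I calibration uses 1000 random sets against a no-effect signature
and checks the nominal-significance rate against the 99% binomial band
around 0.05. All randomness flows from explicit seeds; reports are
byte-identical across reruns of the same configuration.

## Known limitations

- The FDR *q* is the GSEA-style empirical ratio estimate; it is noisy at
  small n_perm and is not a BH-adjusted *P*.
- The permutation null treats genes as exchangeable (no inter-gene
  correlation), which understates null ES spread on correlated data.
- Ward.D on unsquared distances is a historical convention, kept as the
  default for comparability; Ward.D2 is the geometrically consistent
  variant.
- Exposure annotations are consumed as given; curation of exposure risk
  is outside the package.
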