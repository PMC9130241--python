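# Methods

## Count model and differential expression

Counts for gene *g* in sample *i* are modelled as negative binomial with
mean μ, dispersion φ and variance μ + φμ² (φ = 0 is Poisson). The DE
workflow follows the classic small-sample two-group recipe:

- **TMM normalization.** Each sample is compared with a reference (the
  sample whose upper quartile of count proportions is closest to the mean
  upper quartile, unless one is given). Genes with a zero in either library
  are excluded; M = log₂((y/N)/(y_r/N_r)) and A = ½·log₂ of the product of
  the two proportions; the top and bottom 30 % by M and 5 % by A are
  trimmed and the surviving M-values averaged with inverse delta-method
  (binomial) variance weights; the factor is 2 to that mean. Factors are
  rescaled to geometric mean 1. Degenerate inputs: a pair of libraries
  with max |M| < 1e-6 gets factor 1; fewer than 10 genes after trimming
  gives factor 1 with a warning; a single shared gene uses its M alone.
  The implementation reproduces Bioconductor edgeR's `calcNormFactors`
  to ~1e-9 on random fixtures (verified in the test suite by calling R).

- **Common dispersion.** A single φ is estimated by maximizing the summed
  per-gene conditional NB log-likelihood given each gene's within-group
  total, on counts rescaled (and rounded) to the geometric mean of
  effective library sizes. Rounding keeps the conditioning argument exact;
  the golden-section search runs on log φ over [1e-6, 10] to 1e-4. Only a
  common dispersion is fitted — with n = 3 per group, per-gene (tagwise)
  estimates carry little information. With identical replicates the
  likelihood is monotone toward the lower bound and the estimate collapses
  to it.

- **Exact test.** Counts are equalized to a common library size; given a
  gene's total *z*, the two group sums follow the convolution of
  NB(n_A·μ̂, φ/n_A) and NB(n_B·μ̂, φ/n_B) with μ̂ = z/(n_A+n_B); at φ = 0
  this is a binomial split of *z*. The two-sided p-value sums the
  probabilities of all partitions whose point probability is at most the
  observed one (ties included in the rejection mass), so p ∈ (0, 1] and a
  symmetric observation gives p = 1 exactly. A gene with total 0 returns
  p = 1 and log2FC = 0. The log2 fold change is computed on TMM-normalized
  CPM group means with a prior count of 0.5 per group to avoid infinite
  ratios at zero counts.

- **Multiple testing and calls.** BH step-up adjustment
  (fdr_i = min_{j ≥ rank(i)} m·p_(j)/j, clipped at 1, input order
  preserved). A gene is a DEG iff |log2FC| > 1 **and** FDR < 0.05, both
  strict inequalities. The heatmap export uses log₁₀(normalized + 0.001),
  the volcano export −log₁₀(FDR).

The exact test treats the design as two independent groups; tumour/normal
pairing is not modelled.

## Consensus targets and network assembly

miRNA–mRNA pairs are retained when present in ≥ `min_sources` of the
supplied target tables (default 3 of 3, the strict-intersection reading;
the knob exists because database agreement conventions vary). ID matching
is exact string after whitespace trimming — no alias resolution, which is
database-version-dependent. Pairs are then restricted to DEGs of the right
class; an identifier occurring in two classes' DEG sets is rejected as a
namespace collision.

Triples are the complete join of lncRNA–miRNA and miRNA–mRNA pairs on the
shared miRNA. Trend HLH = (up, down, up), LHL = (down, up, down), anything
else is discordant and discarded (counted). Graph nodes are internally
namespaced by type (`lncRNA:FOO`) so symbol collisions between classes are
impossible; exports carry the bare ID plus a type attribute. Degree counts
unique undirected edges (a pair supported by several sources counts once);
hubs are nodes with degree strictly greater than 5 (configurable). The
survival subnetwork is the two-step neighbourhood of the seed mRNAs
(seeds → their miRNAs → those miRNAs' lncRNAs, connecting edges only), so
every retained node lies on a path to a seed; the operation is idempotent.
GraphML and JSON exports round-trip to an identical graph; SIF carries
topology and edge types only (the format has no node attributes).

## Enrichment

One-sided hypergeometric over-representation: with a universe of N genes
containing K set members and a query of n genes overlapping the set in k,
p = P(X ≥ k). The universe is the expression matrix of the relevant class,
not all annotated genes — the query could only ever have come from there —
and genes outside it are dropped from query and sets alike. Significance is
flagged at raw p < 0.05 (the convention of most ORA figure filters, and it
is not stated whether published filters of this kind are adjusted); BH-FDR
is always reported alongside. The scipy hypergeometric survival function
provides the log-space-stable tail; the test suite verifies it against
exhaustive subset enumeration for every parameter combination with N ≤ 12.

## Survival screen

Expression is dichotomized at the median (ties to the low group; a
quantile rule is available — the cut-point convention in published KM
screens is rarely stated, so it is configuration, not assumption). The KM
estimator is the standard product limit over distinct event times;
censored-only times shrink the risk set without adding a step. The
log-rank statistic is (Σ(O₁−E₁))²/ΣV with the hypergeometric variance term
per event time and a 1-df χ² tail; the risky group is the arm with more
observed than expected deaths. No events at all yields χ² = 0, p = 1 with
a warning. The screen applies no multiplicity gate (matching per-gene
p < 0.05 reporting) but emits a BH column. Both KM and log-rank are checked
against lifelines in the tests.

## The synthetic study (what a green test establishes)

Defaults state a desk-scale world: 200 lncRNAs, 150 miRNAs, 500 mRNAs;
3 tumour + 3 normal samples; 20 planted triples with |log2FC| = 3;
φ = 0.1; library sizes uniform in [1e5, 2e5]; decoy rate 0.005 per
possible pair per source; three target sources; 85-patient cohort,
hazard ratio 3, 30 % censoring, baseline exponential scale 1500 days.
Real studies have far larger universes; the package's guarantees are
property-based (error control, recovery, calibration) and do not depend
on universe size, which is chosen so the full suite runs in seconds.

Choices worth knowing:

- Baseline abundances are log-uniform over four decades (exercises
  normalization). Planted DE genes draw from the top two decades: a gene
  with expected count below ~1 cannot exhibit a detectable two-fold
  empirical ratio at n = 3, so planting signal there would state a world
  whose truth is unrecoverable by design.
- The paired design is simulated as independent samples sharing baselines
  (no patient random effect), matching the two-group test downstream.
- Decoy interactions never join two planted DE genes (unless
  `allow_confusable=True`) — a sufficient condition for decoys never
  forming direction-consistent triples among planted genes, keeping
  recovery metrics interpretable.
- Survival: for each planted survival gene the two median-split halves of
  the cohort differ in event rate by exactly `hazard_ratio`; the contrast
  is centred (×√HR vs ÷√HR) so that effects of many planted genes multiply
  without driving the absolute time scale to absurd values. Censoring is
  an independent coin flip followed by uniform shrinkage of the event time.
- Everything derives from one integer seed through separate child streams
  (counts, interactions, gene sets, survival), so outputs are bit-identical
  across runs given the seed.

What the generator does **not** emulate: isoform structure, patient random
effects, GC/length biases, correlated miRNA target programs, non-exponential
hazards, or informative censoring. A green recovery test therefore shows the
pipeline correctly inverts its stated generative model — not that it is
robust to every artefact of real libraries.

## Numerical notes

- Exact-test enumeration is O(z) per gene (closed-form log-pmfs via
  `gammaln`), so a whole matrix costs on the order of its total read count.
- p-values are floored at the smallest positive double before −log₁₀ for
  volcano export.
- BH is implemented once (`diffexpr.bh_adjust`) and reused by enrichment
  and the survival screen.
- The pipeline manifest contains every stage's before/after counts and is
  deterministic given (config, seed); timestamps are the only varying
  fields.

## Known limitations

- Two-condition designs only; no GLM/quasi-likelihood path, no batch
  correction.
- Common dispersion only; genuinely gene-specific overdispersion will make
  the exact test anti-conservative for the most variable genes.
- No sequence-based target prediction: interaction tables are taken as
  given.
- Survival screening is marginal per gene (no Cox adjustment, no optimal
  cut-point search).
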