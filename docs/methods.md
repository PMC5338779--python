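# Methods

This note records the models, rules and numerical conventions implemented
in `channelscreen`, the choices made where the procedure was genuinely
open, and what the synthetic-data tests do and do not establish.

## The screening procedure

The pipeline identifies genes (in the motivating application: druggable
ion channels) enriched in tumor stem-cell isolates relative to normal
neural controls, then relates the candidates to molecular subtype,
anatomic tumor region and patient survival. All stages operate on
gene × sample abundance matrices tagged with their unit (raw counts, CPM
or FPKM); operations declare which currencies they accept and refuse the
rest.

### Normalization (counts → CPM)

Between-sample scale factors use the trimmed mean of M-values (TMM).
For sample *k* against a reference *r*, with counts *y* and library sizes
*N*:

- M_g = log2[(y_gk/N_k)/(y_gr/N_r)], A_g = ½·log2[(y_gk/N_k)(y_gr/N_r)],
  over genes positive in both samples (zero-count genes are excluded
  *pairwise*, per comparison, not globally);
- genes are double-trimmed by rank: the central 40 % of M (30 % trim per
  tail) intersected with the central 90 % of A (5 % per tail);
- the factor is 2 raised to the inverse-variance weighted mean of the
  surviving M values, with delta-method binomial weights
  w_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr);
- the reference is the sample whose upper-quartile/library-size ratio is
  closest to the cohort mean of that ratio; factors are rescaled to
  geometric mean 1.

The trim fractions (30 % on M, 5 % on A) are the method's published
defaults; the citing study names the method without parameters. The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
1 × 10⁻⁸ on a frozen fixture and matches an independently coded
step-by-step evaluation on random matrices (tested).

CPM is count/(library size × factor) × 10⁶. Sequencing replicates (2–3
per isolate) are averaged arithmetically *on the CPM scale* to one column
per isolate; group means average the isolate columns. Averaging CPMs, not
logs, follows the upstream study's stated procedure.

### Fold-change classification

log2FC = log2(tumor mean / control mean) per gene, with two explicit
zero policies: `exclude_zero_denominator` (genes with a zero control mean
are excluded and counted) and `replace_with_pseudo` (zeros on either side
replaced by 0.01 before the ratio). Genes are called tumor-enriched at
log2FC ≥ +2, control-enriched at ≤ −2 (both inclusive), else unchanged.
Both policies agree exactly wherever the denominator is positive
(tested).

### Signal2Noise ranking and enrichment score

Genes are ranked by s = (μ_t − μ_c)/(σ_t + σ_c) over isolate-averaged
columns, with each sample standard deviation (ddof = 1) floored at
max(σ, 0.2·|μ|, 0.04) — the floor convention of the reference enrichment
tool, exposed as parameters since the citing study names only the metric.
Whether σ should be computed over replicate-level or isolate-averaged
columns is not stated upstream; isolate-averaged is the default (matching
the replicate-averaging step) with a flag to override. Ties are broken
lexicographically by gene identifier so reruns are bit-stable.

The enrichment score of a set S against the ranked list is the signed
extremum of the weighted running sum: a member at position *i* adds
|s_i|^p / Σ_{j∈S}|s_j|^p (p = 1 by default), a non-member subtracts
1/(N − |S|). If every member score is zero at p = 1, the walk falls back
to equal hit weights (the p = 0 limit) rather than dividing by zero. The
leading edge is the members at or before the extremum (at or after, for
negative ES).

### Permutation null, p-value and NES

Two null schemes are implemented: `gene_set` (random same-size sets from
the ranked universe; the default, because a 20-vs-5 cohort admits few
distinct label permutations) and `phenotype` (tumor/control labels
permuted over columns, ranking recomputed). The p-value is the
sign-conditioned tail with add-one smoothing,
p = (1 + #{same-sign null ≥ ES})/(1 + #same-sign null), and
NES = ES / mean(|same-sign null ES|). Conditioning on the sign makes p
exactly (discretely) uniform under a random set — verified by a
Kolmogorov–Smirnov test over 200 replicates of 1000 permutations — at the
cost that the attainable minimum is ≈ 2/(n_perm) rather than
1/(n_perm + 1); the result object reports the same-sign null count so the
floor is always explicit.

### Candidate selection and family summaries

Candidates are the top-k genes (k = 40 by default) from the
tumor-enriched end of the ranking that also have mean tumor CPM ≥ 1; both
drop stages are recorded in an audit. Family summaries use
exclude-policy fold changes only: per family, the mean log2FC, the
proportion of members with *linear* fold change strictly > 2, and the
mean tumor CPM; families with ≤ 1 usable member are omitted.

### Subtype classification

Four-class centroids (Classical, Mesenchymal, Neural, Proneural) are the
per-gene *median* over labelled reference samples, restricted to a
signature gene list (nominally 770 genes; absent genes are reported and
dropped). A sample is assigned by maximal Spearman correlation against
the centroids (average-rank ties, requiring ≥ 10 shared signature genes);
replicates are classified separately and combined by majority, with ties
going to the tied label of highest mean correlation and residual ties to
the fixed subtype order above (warned). Only the Spearman-centroid route
is implemented; the consensus operation accepts any per-replicate calls,
so an alternative classifier can be plugged in. Hierarchical clustering
supports the two recipes used upstream — euclidean/unweighted-average
(UPGMA) and manhattan/complete — and emits newick with merge heights as
branch lengths. Expression is not log-transformed before clustering
unless requested.

### Regional profiling

FPKM values are averaged in two levels, replicates → sample and
samples → region, over the seven atlas compartments (LE, IT, CT, PZ, PAN,
HBV, MVP). Rules, all parameterized:

- **edge enrichment**: mean(LE, IT) / mean(other region means) ≥ 2.
  0/0 is defined as 1 (absence of signal is not enrichment); positive/0
  is infinite and flagged.
- **abundance classes**: high ⇔ ≥ 5 FPKM in ≥ 1 region (inclusive);
  low ⇔ < 1 FPKM in every region (strict); intermediate otherwise.
- **family-by-region proportions**: fraction of members with region mean
  strictly > 1 FPKM, families with ≥ 3 members only.
- **majority expression**: > 50 % of a region's per-sample values at or
  above a threshold (per-sample values are retained in the profile for
  this).
- **cell-type specificity** (for normal cell-type panels): low-abundance
  if no cell-type mean reaches 1 FPKM; otherwise specific to the top
  type if its mean is ≥ 2× the runner-up, else multi-type. The 2×
  dominance rule is this package's declared convention — the source
  analyses never define "specifically enriched" — and is a parameter.

### Survival analysis

Cohorts are stratified by expression either at the 0.10/0.90 quantiles
(low ≤ Q(0.10), high ≥ Q(0.90), middle excluded; linear interpolation
between order statistics, the type-7 convention) or by a median split
(high strictly above; an externally supplied median may override).
Kaplan–Meier curves and the two-group log-rank (Mantel–Cox) test are
computed via `lifelines`; the curve's median is the first time S(t) ≤ ½.
The KM estimate is verified against a brute-force product-limit
evaluation and the log-rank p against a 20 000-draw permutation oracle.
Mann–Whitney tests use the exact distribution for min(n₁,n₂) ≤ 8 without
ties and the tie-corrected normal approximation otherwise, *without*
continuity correction so the two-sample case agrees with Kruskal–Wallis
to 10⁻⁶ on tie-free data. Mutation–expression associations run
Mann–Whitney per (gene, mutation), skipping mutations carried by fewer
than 3 isolates or lacking any wildtype isolate. No multiple-testing
correction is applied across genes — results report per-test p-values
and the number of tests, matching the per-gene reporting convention of
the motivating study.

## Synthetic-data generators

All generators are pure functions of their configuration, seed included,
and return the ground truth alongside the data.

- **Screen cohort**: negative-binomial counts (variance μ + φμ², φ = 0.1
  by default, via a gamma–Poisson mixture) around lognormal per-gene
  baselines (ln-scale mean 4.0, sd 1.5, chosen to give a realistic
  dynamic range of roughly 1–10⁴ CPM). Default design mirrors the study:
  20 tumor vs 5 control isolates, 3 replicates each, library sizes
  uniform on [0.8, 1.2] × 10⁶. Planted genes (5 % by default) have their
  tumor means multiplied by 2^effect (effect 3 by default; the upstream
  work reports no effect-size distribution, so this is a calibration
  choice, not a claim). Replicates of an isolate share a gene-level
  lognormal perturbation (sd 0.1) so replicate averaging is a meaningful
  stage.
- **Regional atlas**: per-sample FPKM = region mean × exp(noise·z), with
  configurable samples and replicates per region; at noise 0 aggregation
  recovers the generator means exactly (tested).
- **Survival**: exponential event times with hazard
  h₀·exp(β·z(expression)); censored samples (probability = censor rate)
  report a uniform fraction of their event time. This is a convenience
  scheme, not independent administrative censoring; under β = 0 it still
  satisfies the null exactly, which is what the calibration tests use.
- **Subtype reference**: signature genes split into four equal blocks;
  centroid k adds the separation parameter to block k on top of a shared
  uniform(2, 10) baseline; samples are centroid + gaussian noise clipped
  at zero. At separation 0 the centroids coincide and out-of-sample
  assignment is at chance (≈ 25 %).

What the generators do *not* emulate: batch effects beyond the isolate
random effect, gene–gene correlation, length-dependent FPKM artifacts,
subtype-correlated expression in the screen cohort, or informative
censoring. Passing tests therefore demonstrate correctness of the
*procedure* under its stated assumptions, not robustness to every
real-data pathology.

## Numerical conventions and degenerate inputs

- Duplicate gene or sample identifiers, negative abundances, missing
  entries and malformed lines are rejected with coordinates, never
  repaired. Gene identifiers are opaque and case-sensitive.
- A sample pair whose genes are all trimmed away gets TMM factor 1 with a
  warning; a zero library size is an error.
- A constant expression vector is an error for Spearman classification
  and for quantile stratification (strata would be empty or total).
- All-censored survival tables yield a flat curve with undefined median
  (`None`), not an error.
- Dendrogram heights are asserted non-decreasing root-ward on every tree.
- Every stochastic routine takes an explicit seed; derived sub-streams
  keep generators independently reproducible.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run at desk scale: TMM oracle
agreement on 20-gene matrices (20+ draws); enrichment-score oracle on 50
random list/set instances; null calibration with 200 × 1000 permutations;
planted-recovery over 50 (tests) or 25 (script) seeded cohorts of 1000
genes; 500-replicate log-rank type-I-error simulation at cohort size 500;
exhaustive Mann–Whitney enumeration up to n₁+n₂ = 12. These sizes were
chosen as the smallest at which each property is statistically decisive.

## Known limitations

- The log-rank test is limited to two strata (every comparison in the
  motivating analyses is two-group); no Cox regression, competing risks
  or interval censoring.
- The asymptotic log-rank is anti-conservative for very small strata
  (~7 % rejection at 12 vs 12); the type-I guarantee is stated at the
  default cohort size (50 vs 50 extremes of 500).
- No FPKM computation from counts: regional FPKM tables are consumed as
  provided.
- No multiple-testing correction across gene sets or genes (by design;
  see above).
- The gene-set permutation null fixes the ranking and randomizes
  membership; it does not propagate between-sample variability the way
  phenotype permutation does, and is the default only because tiny
  class sizes make phenotype permutation coarse.
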