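# Methods

## The harmonization model

The unit of analysis is a *comparison*: one treated-vs-control contrast
from one experiment, annotated with cell line, compound and compound
class, dose (nM), duration (h), platform and batch (a batch groups
contrasts sharing a control set). Differential-expression model fitting
happens upstream (DESeq2/limma outputs are ingested); the one
fold-change computation owned here is the no-replicate fallback:
log2(CPM + 1) differences with CPM computed on TMM-scaled effective
library sizes.

**TMM.** Factors follow the trimmed-mean-of-M-values construction: M and
A values against a reference sample (the one whose upper-quartile CPM is
closest to the mean upper quartile), genes with zero counts in either
sample excluded, double trim of 30% on M and 5% on A, precision-weighted
mean of the surviving M values (weights from the delta-method binomial
variance; an unweighted variant is available and is what the plain
"trimmed mean" oracle reproduces), and a final geometric-mean-1
renormalization. Genes with zero counts in every sample are dropped
before normalization. The trim fractions and reference rule are
conventional defaults, exposed as arguments — no authoritative values
exist for them in this pipeline's provenance.

**Regulatory percentiles.** Within one comparison, genes with positive
log2FC are ranked ascending and mapped to (0, +100] as `100·rank/u`
(u = up-pool size); negative genes symmetrically to [−100, 0) by
magnitude rank; zeros stay 0. Ties take mid-ranks, so untied extremes hit
±100 exactly. Rank scaling is the primary convention (a linear
fold-change scaling, `scale="fc"`, is kept as a switch): percentile
semantics are robust to platform-specific fold-change compression, which
is the point of the harmonization. A gene absent from a platform's
universe is *missing*, never 0; the presence filter retains genes
non-missing in ≥ 80% of scoped comparisons (boundary inclusive).

## Cross-comparison statistics

- *Heterogeneity*: log₁₀((sd/|mean|)²) per gene over ≥ 3 observations;
  zero-mean and zero-variance genes are excluded and reported rather than
  silently dropped, since CV is undefined for them.
- *Consensus / bidirectional calls*: top-decile membership is defined on
  the percentile value (≥ +90 / ≤ −90), equivalent to per-comparison rank
  deciles under rank scaling. Consistency denominators count only
  comparisons where the gene is observed; otherwise every array-absent
  gene would be structurally penalized. "At least" thresholds are
  inclusive; the Δ-percentile discordance cut is strict, as stated.
- *Mixed model*: `pct ~ C(cell_line) + C(modality) + C(drug_type) *
  duration`, random intercept per batch, REML via statsmodels MixedLM.
  Duration enters as continuous hours and is mean-centered so the
  drug-type main effect is the effect at the average duration rather than
  an extrapolation to 0 h (with an interaction present, the uncentered
  main effect has inflated SE and answers the wrong question).
  Single-level categorical terms are dropped with a warning;
  non-convergence and singular designs are flagged on the result, never
  raised. The lbfgs optimizer fails with LinAlgError on a sizable
  fraction of these small designs; the default optimizer with a Powell
  fallback is used. BH adjustment across genes is applied per term.
- *Similarity search*: pairwise-complete Pearson r against the query
  profile, two-sided t-test on n−2 df, BH across genes.

## Enrichment

The preranked GSEA statistic is the weighted KS running sum: hits
increment by |rank value|^weight (normalized), misses decrement uniformly;
the ES is the extremum of largest magnitude, with positive deviations
winning ties (to a 1e-9 tolerance, so float noise on exact ties cannot
flip the sign). Nulls come from gene permutation: per set, `n_perm`
random same-size position sets. NES divides ES by the mean |null ES| of
the same sign; the FDR compares observed |NES| to the pooled same-sign
null NES distribution, clipped to 1. A set spanning the whole universe
has ES 0 by definition. Defaults (min 5, max 1000, 1000 permutations,
seed 6, weight 1) reproduce bit-identically under a fixed seed.

Fisher over-representation uses the one-sided hypergeometric tail on the
(overlap, query-only, term-only, neither) table with BH across terms.
The single-sample scorer is a deliberate, documented stand-in for
GSVA-style scoring: within-sample mid-ranks standardized by the exact
uniform-rank moments, averaged over set genes. It is monotone in set-gene
expression and scores a constant sample 0, which is all the
classification stage requires; it does not reproduce GSVA's KS kernel or
its between-sample normalization. The Mode-2 signature screen uses the
geometric mean of signature genes (a +1-minus-minimum offset is applied,
with a warning, if non-positive values occur, as with some array
intensities) and a two-sided Welch test on log signature values — the
two-group test is not specified in the source, Welch is the robust
default. The Oncotype weighted impact applies the published
recurrence-score coefficients to group-mean regulatory percentiles, with
CTSL2 and GUSB excluded from the panel.

## Classification

Integrated score = activation-set score − repression-set score (signature
construction cut: average percentile beyond ±60, strict). The logistic
fit is univariate fixed-effect maximum likelihood; perfect separation is
flagged and the rank-based ROC/AUC still returned, since the AUC —
trapezoidal area over distinct-threshold ROC points, identical to the
tie-corrected Mann–Whitney statistic — is separation-proof. A per-cohort
intercept is a documented extension point rather than a default: the
random-effects structure of the original multi-cohort fit is not
recoverable, and the synthetic cohort has no cohort strata.

## Cistrome

Coordinates are BED 0-based half-open. Gained peaks are case peaks with
less than `min_overlap_bp` (default 1) shared bases against every control
peak. Regulatory potential sums, over peaks whose midpoint lies within
±100 kb of a gene's TSS, the decay `exp(−(0.5 + 4Δ))`, Δ = distance /
window — the exponential form of the BETA-minus family, with linear and
flat kernels as alternatives since the original tool's exact kernel is
configuration, not contract. Peak position is the interval midpoint
(summit columns are not guaranteed in ingested BEDs). Averages over
multiple gained-peak sets divide by the number of tables scoring the
gene.

## The synthetic world

`generate_comparisons` draws, for gene g in comparison c:
`log2FC = mult(class_c)·effect·loading_g + cellline + dose_coef·log10(dose)·loading_g + batch + N(0, σ)`
with loadings |N(1, 0.25)| (signed by role), class multipliers
SERD 1.0 / SERM 0.6 (tamoxifen-class responses are weaker and more
heterogeneous), cell-line and batch effects of sd 0.2, noise σ = 0.8
(strong preset: effect 3, σ = 0.5), and 25% microarray comparisons drawn
from a reduced gene universe (15% of genes absent) to exercise the
presence filter. Core-up/down fractions are 4% each: the planted
consensus pool must fit inside the up-pool's top decile (~5% of genes),
or the labels would promise what the world cannot contain. Bidirectional
genes (2%) respond up in 30% and down in 20% of comparisons. A separate
generator plants those proportions directly on the percentile scale
(±95 against noise sd 20) for testing the calling thresholds in
isolation, and a latent-loading construction backs the similarity-search
checks.

The regression generator plants percentile-scale drug effects on an
identifiable design: batches block consecutive comparisons so both drug
classes occur within each batch (batch sd 8), and the remaining
covariates are drawn independently — cyclic assignments are avoided
because they silently produce collinear designs. The null configuration
(no fixed effects, 60 comparisons, 15 batches) is the calibration world
for the mixed model's p-values; 60 observations keep the Wald normal
approximation adequate.

The cohort generator shifts case samples by ±1 sd of log2 expression on
50 activation and 50 repression genes; the peak generator plants 4
peaks within ±10 kb of each of 10 target TSSs on a 2×3 Mb toy genome
(plus unlinked gained peaks), tight enough that a target outranks the
TSS neighbors that unavoidably share its planted cluster at ~30 genes/Mb
density.

What a green recovery test establishes: the statistics identify planted
structure through the full harmonize→call path under realistic nuisance
variation. What it does not: performance on real GEO depositions, with
their correlated batch structure, non-Gaussian noise, annotation drift
and unmodeled platform biases; nor any of the original study's empirical
correlation values, which derive from hundreds of curated experiments.
Recovery of planted consensus genes is assessed over the analyzable
universe — genes removed by the 80% presence filter (absent from the
array platform) are not recoverable by any cross-comparison statistic
and are excluded from the recall denominator.

## Numerical conventions

- Boundary comparisons on stated thresholds ("at least", "≥") use a
  1e-12 tolerance so float representation cannot flip a printed-value
  boundary.
- Missing values propagate as NaN; they are never imputed.
- All generators fan a master seed into per-artifact child streams via
  CRC32-keyed SeedSequences, so artifacts are independently reproducible.
- Dose strings accept nM, µM, mM, pM and mol/L variants; unparseable
  doses become null with a logged warning rather than an error.

## Known limitations

- The mixed model's p-values are Wald-based; for designs much smaller
  than ~40 observations they will be anticonservative.
- The GSEA FDR follows the sign-stratified permutation convention
  without the monotonicity post-pass some implementations add; values
  are comparable but not bit-identical to other tools.
- The single-sample scorer is not GSVA; scores are comparable within a
  matrix, not across matrices.
- Microarray probe-to-gene mapping, batch-effect *correction* (as
  opposed to modeling) and upstream peak calling are out of scope.
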