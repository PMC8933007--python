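# Methods

`senescape` implements the statistical procedures used to dissect a
replicative-senescence time course across assays: ATAC-seq chromatin-state
accounting, genomic-domain overlap statistics, motif regression of
accessibility change, paired-control trend testing for metabolite/protein
abundances, single-cell senescence scoring with pseudobulk aggregation, and
pseudotime-trajectory clustering.  Every stage is exercised end-to-end on
synthetic data whose planted structure matches what the analyses assume, so
each estimator can be checked against a known truth table.

## Study design being modeled

Primary fibroblasts are passaged to replicative senescence; cumulative age
is tracked as the population doubling level (PDL), incremented per passage
by log2(harvested cells / seeded cells).  A telomerase-immortalized line is
grown and sampled in parallel as a longitudinal control: it shares every
day-of-sampling batch influence but none of the senescence trend.  Samples
at increasing PDL are profiled by ATAC-seq, RNA-seq, scRNA-seq, proteomics
and metabolomics; the analyses ask where accessibility changes concentrate
in the genome (chromatin states, nucleolar- and lamin-associated domains —
NADs and LADs), which transcription-factor motifs predict those changes,
and how gradually the senescence expression program engages at the
single-cell level.

## Core models and procedures

### Linear trend model

For each feature (metabolite, protein, peak, FRiP value) with log-scale
values y_it at replicate i and timepoint t, we fit

    y_it = beta0 + beta1 * T_t + eps_it

by per-feature OLS, test H0: beta1 = 0 with a two-sided t statistic at
n − 2 degrees of freedom, and control FDR across features with
Benjamini–Hochberg.  The covariate T_t is used exactly as supplied (a
passage vector such as (33, 37, 46, 50) for metabolites); no shrinkage or
moderation is applied across features.  The implementation is closed-form
normal equations (vectorized over features); the tests verify it against an
independent statsmodels OLS fit to 1e-10.  A constant covariate, or fewer
than three distinct covariate values, is an error.

### Paired-control batch correction

Metabolite values are first scaled by a protein-concentration factor
(median concentration of the sample's group divided by the line's overall
median; multiplied as specified, with a config switch for division since
the intended direction is ambiguous).  Each wild-type sample is then
divided by its temporally paired control sample (replicate-index matched;
per-timepoint control mean when replicate counts differ), and expressed as
log2 fold change against the reference timepoint.  Any multiplicative
factor shared by both members of a pair — the sample-day batch effect —
cancels exactly; the tests assert cancellation to 1e-10.  Zero or missing
abundances are hard errors: no imputation or pseudocounts are applied to
measured abundances.

### Chromatin-state accounting

Peaks are assigned to a 25-state genome segmentation (grouped into
promoter / enhancer / transcription / miscellaneous, with the mark-free
"undefined" state inside miscellaneous) under a strict containment rule: a
peak entirely within one state instance is "inside"; a peak containing one
or more instances of a single state and touching no other state is
"inside_feature"; anything else — spanning states, or partial single-state
overlap without containment — is discarded.  Zero-length boundary contact
does not count under half-open coordinates.  A brute-force per-basepair
oracle validates the assignment on small fixtures.

Read-distribution fractions across states (or the 4 categories) are
computed from per-state-instance counts, summed per state before
normalization.  Quantile normalization (per-rank row means, ties receiving
the mean of their spanned reference values) matches the original read
count processing and is idempotent by construction.

For fold-change summaries we deliberately use sequencing-depth
normalization (counts scaled by relative library size), not quantile
normalization: when accessibility genuinely shifts one way across a large
peak class — precisely the planted structure here — any
distribution-matching or median-of-ratios normalization absorbs part of
the shift into the size factors and biases per-domain medians by ~0.1–0.3
log2 units.  Depth is an external observable (total sequenced reads), so
this estimator stays unbiased under one-sided global change.  Per-state
median log2 fold changes use a +1 pseudocount against the mean of the
reference-timepoint replicates, include only peaks below the configured
adjusted-p cutoff (default 0.001), and report missing (never 0) for states
with no qualifying peak.

### Domain-overlap statistics

The permutation overlap test counts target genes intersecting ≥1 bp of a
domain set and compares against null gene sets resampled from the universe
within expression deciles, so the null preserves the targets' expression
profile (domains are gene-poor, making expression matching essential).
z = (observed − null mean)/null sd; the empirical p uses the add-one rule
and is never 0; a degenerate null (sd = 0) is flagged with z = 0.  With
matching disabled on an enumerable universe the test converges on the
hypergeometric tail (asserted in the tests).

The domain shift test is a Wilcoxon rank-sum comparison of per-peak log2
fold changes inside vs. outside a domain class, exact for tie-free groups
of ≤25, tie-corrected normal approximation otherwise.  Motif-in-domain
enrichment is a one-sided hypergeometric upper tail.  The motif × domain
interaction ("greater-than-additive" accessibility gain for motif-bearing
peaks inside a domain) is the one-sided t-test on the interaction
coefficient of OLS: log2FC ~ 1 + motif + domain + motif·domain.

### Motif regression

Motif involvement is assessed two ways.  Gene-centric: for each motif, an
inclusive upper-tail binomial test of its frequency among target peaks
(near a gene set and significantly changing) against the frequency among
all other peaks; degenerate backgrounds (frequency 0 or 1) are handled
exactly and flagged.  Gene-independent: an L2-penalized logistic
regression on the binary peak × motif matrix separating significantly
up- from down-accessible peaks.  Features stay raw binaries (coefficients
read as per-motif log-odds) and the intercept is unpenalized.  A
stratified 2/3 train split reports held-out AUC via the rank statistic
(equal to the probability a random positive outscores a random negative);
coefficients are then averaged over 10 bootstrap refits on all labeled
peaks and motifs ranked by mean coefficient.  Ten refits on identical data
would be identical, so bootstrap resampling is the reading under which
averaging carries information; a config switch restores the degenerate
identical-fit variant.  The ridge penalty defaults to 1.0 and can be
selected by 5-fold cross-validated log-loss over a small grid.

### Single-cell stages

Counts are library-size scaled to the median depth and log1p transformed
for scoring — a monotone normalized scale; heavier variance-stabilizing
transforms are out of scope and scoring does not need them.  Module scores
subtract, from the mean expression of a gene set, the mean of a control
pool drawn per set gene from the same average-expression bin (24
equal-count bins, 100 controls per gene, without replacement within a
bin).  Cell-cycle phase is called from S and G2M scores: both ≤0 → G1,
otherwise the larger score, positive ties → S (logged).  Signature
specificity takes two differential-expression tables and returns genes
induced uniquely in each.  Pseudobulk sums counts within (PDL, phase)
groups, keeps groups with strictly more than 15 cells, retains the top
8000 genes by total counts (lexical tie-break), and computes log2 CPM+1
fold changes within phase against that phase's earliest PDL.

### Trajectory clustering

Cells are partitioned into 60 equal-width pseudotime bins; a cubic
smoothing spline (stiffness by generalized cross-validation; an
interpolating cubic for exactly 4 non-empty bins) is fit to the non-empty
bin means, evaluated at every bin center, and min-max scaled to [0, 1]
(constant profiles are flagged and set to all-zero, since 0/0 scaling is
undefined).  Genes are clustered by K-medians under cosine similarity
(k = 25 by default): assignment to the most-similar median,
coordinate-wise-median update, k-means++-style cosine seeding, empty
clusters re-seeded from the worst-fit gene.  The coordinate-wise median
does not mathematically guarantee a non-increasing cosine objective, so
the iteration carries a monotone safeguard: an update that would increase
the summed cosine distance is reverted and iteration stops.  Clusters are
labeled early / transition / late by the argmax bin of their median
profile (bins 1–20 / 21–40 / 41–60, ties to the earliest bin).

## Synthetic data: what it emulates

All generators are pure functions of a spec + seed (per-component
sub-streams of one master seed) and emit truth tables.

- **Genome** (2 chromosomes × 5 Mb): the 25-state segmentation is laid
  down by chunking each state's bp share (the undefined state as long
  ~250 kb runs holding half the genome, other states as ~10 kb chunks) and
  shuffling, so bp proportions are exact up to chunk rounding.  NADs and
  LADs (10 per chromosome, 150 kb) are placed wholly inside undefined runs
  for a fixed ceil(bias·n) of domains (bias 0.9), guaranteeing the
  undefined-bp fraction of domain territory; genes avoid NADs at a 0.25
  density ratio and carry log-normal expression scores.
- **ATAC counts**: mu_ps = L_s · b_p · 2^(f_p · x_s) with x the PDL scaled
  to [0,1], negative-binomial with Var = mu + alpha·mu² (alpha → 0 is
  Poisson).  Planted f_p medians: 0.98 for NAD peaks, 0.24 for
  LAD-not-NAD, 0 elsewhere (sd 0.25 / 0.25 / 0.10).  Peak placement is
  accessibility-weighted — only 15% of peaks land in undefined-state
  territory — because real peak atlases concentrate in open chromatin and
  unchanged background peaks must dominate for normalization to behave as
  it does on real data.  Defaults of 3 replicates at 7 PDLs (20–50) and
  dispersion 0.02 (biological CV ~14%, typical for cultured cell lines)
  give the q < 0.001 peak-selection step realistic power: with weaker
  designs essentially no peak of effect ~1 log2 unit clears an
  adjusted-p 0.001 cutoff at this scale and the significance-gated
  summaries would be vacuous.
- **Motif labels**: presence i.i.d. Bernoulli(0.1); labels Bernoulli on
  logistic(intercept + m·beta).  Default planting: one coefficient +8 with
  intercept −4, chosen analytically so the planted motif nearly determines
  the label: P(up|motif) = 0.982, P(up|no motif) = 0.018, giving an
  analytic AUC ≈ 0.93.  A single binary feature cannot exceed AUC ≈ 0.84
  at weaker effects, so a "strongly predictive motif" condition requires
  near-determinism.
- **Cells**: 500 cells at each of 6 PDLs (25–50), 2000 genes.  The
  senescence program (200 genes) is multiplied by 2^intensity with
  intensity = slope·x(PDL) + N(0, 0.1) in every cell regardless of phase —
  the "gradual in all phases" structure.  Phases follow a schedule whose
  cycling fraction falls from 0.55 to 0.10 across PDL; S and G2M marker
  sets (50 genes each) are boosted 1.5 log2 units in their phase.
- **Metabolites**: value = exp(base_m + trend_m·x_t + batch_t + noise),
  timepoints (33, 37, 46, 50) × 3 replicates; the control line has trend 0
  but the identical batch_t — so paired division cancels batches exactly.
  Half the metabolites are null; the rest have |trend| in [0.5, 1.5]
  (natural-log units per unit scaled time).
- **Pseudotime profiles**: Gaussian-bump archetypes centered at 0.15 /
  0.50 / 0.85 (width 0.12) peaking in each third of pseudotime, 100 genes
  per archetype, 3000 cells, additive N(0, 0.1) noise.

What the generators do **not** emulate: read-level artifacts (fragment
sizes, duplicates, GC bias), peak-calling uncertainty, mean-dependent
dispersion trends, dropout structure beyond NB sampling, doublets/ambient
RNA, correlated genes, UMAP geometry, or pseudotime inference error
(pseudotime is an input).  Passing tests therefore demonstrate that the
statistical machinery recovers the planted structure under the assumed
models — not that the models capture every property of real libraries.

## Numerical choices and degenerate inputs

- Empirical p-values use the add-one rule and are never 0; permutation
  nulls with sd = 0 report z = 0 with a flag.  The overlap count statistic
  is discrete, so a fixture-conditional test level sits between atoms of
  its null pmf and the add-one rule rounds conservatively; calibration
  checks therefore average over target-set sizes (150–350 genes).
- Exact branches: rank-sum enumeration for tie-free groups ≤ 25; binomial
  and hypergeometric tails are exact (inclusive upper tails).
- Quantile normalization resolves within-column ties by the mean of the
  reference values the tie block spans; single-column input is returned
  unchanged with a warning.
- BH adjustment enforces monotonicity by a reverse cumulative minimum and
  caps at 1.
- Tie-breaks are deterministic everywhere: nearest-gene ties go to the
  smaller gene start then lexical id; gene-ranking ties are lexical;
  trajectory argmax ties go to the earliest bin; positive phase-score
  ties go to S.
- The PDL increment is log2(harvested/seeded) — the count of population
  doublings, additive over passages.
- Simulation scales (5000 peaks, 100 motifs, 3000 cells, 100 metabolites,
  300 trajectory genes; 300–500 replicate simulations for calibration and
  power estimates) were chosen so every suite completes in minutes on one
  CPU while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The ridge model's coefficients are on the raw-binary feature scale;
  motifs with very low presence frequency get noisier coefficients, and no
  redundancy reduction is applied across correlated motifs.
- Depth normalization relies on library size being an adequate proxy for
  sequencing effort; it does not correct composition at the
  state-fraction level (the quantile-normalized path is provided for
  that analysis).
- The paired division requires a same-timepoint control with nonzero
  abundance for every metabolite; sparse metabolomes would need an
  upstream filter, not imputation.
- K-medians with cosine similarity is a heuristic; different seeds can
  yield different local optima at k = 25 (recovery is exact in the planted
  3-archetype setting).
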