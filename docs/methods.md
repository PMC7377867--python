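# Methods

This package reimplements an integrative epigenomic/genomic subtyping
analysis for melanoma-like tumor cohorts: identify genes whose expression is
driven by copy-number dosage (CNVcor) or promoter methylation (METcor),
cluster samples on those gene sets by consensus NMF and by a joint
latent-variable model, and characterize the resulting subtypes by survival,
abnormality-burden linkage, and differential molecular features. Because the
original cohort-scale inputs are not redistributable, the package ships a
synthetic multi-omic cohort generator whose planted structure makes every
stage testable as a parameter-recovery problem.

## The synthetic cohort model

`melsubtypes.synthetic.generate_cohort(SimConfig(...))` draws, per cohort:

- **Subtypes.** `n_subtypes` (default 4) latent labels, multinomial with
  `subtype_proportions` (default uniform), over `n_samples` (default 200).
- **Copy number.** Segment-level log-ratios over a toy genome of
  `n_chromosomes` (default 4) chromosomes with p/q arms, genes 10 kb apart.
  Background genes share segment blocks of up to 8 consecutive genes with
  N(0, 0.10) block noise; each of the `n_cnvcor_genes` (default 100) planted
  dosage genes sits in its own segment with a per-gene, per-subtype mean
  drawn from N(0, 0.4) plus N(0, 0.3) within-subtype noise. The gene-level
  matrix equals what `map_segments_to_genes` recovers from the written SEG
  file (tested).
- **Methylation.** Beta values per probe; every gene has a promoter probe
  (CpG island, within 2500 bases upstream of the TSS) and a deterministic
  subset of genes has extra Shore/Shelf/open-sea probes. Planted `n_metcor_genes`
  (default 100) genes carry subtype means N(0, 0.22) plus N(0, 0.10) noise
  around a U(0.35, 0.65) baseline on their promoter probe; background genes
  get U(0.25, 0.75) baselines with N(0, 0.08) noise. A small missingness
  layer (2% random cells plus 1% of non-promoter probes at 40% missing)
  exercises filtering and imputation.
- **Burden coupling.** Each sample has a latent bivariate-normal pair with
  correlation `burden_coupling` (default 0.6). Each latent maps through the
  normal CDF to an abnormal fraction in [0.05, 0.30]; that fraction of genes
  is pushed to copy-number gain/loss (|shift| in [0.5, 0.9], random sign, at
  segment-block granularity) or to methylation extremes (beta in
  (0.85, 0.98) or (0.02, 0.15)). Because the CDF transform is monotone, the
  realized correlation between per-sample abnormal fractions is slightly
  below the latent correlation ((6/pi)·asin(rho/2) ≈ 0.97·rho for uniforms),
  well inside the ±0.15 recovery band the tests use.
- **Expression.** log2 expression = N(7, 1) baseline + `cnv_effect`
  (default +1.0 log2-units per CNV unit) × the gene's final CNV value for
  planted dosage genes + `met_effect` (default −2.0 log2-units per beta
  unit) × the promoter-beta deviation for planted methylation genes +
  N(0, `noise_sd`=0.5). Overlap genes (default 30) receive both terms.
  Counts are a negative-binomial observation layer (dispersion 0.1) on
  2^log2-expression with log-normal(0, 0.2) library-size factors.
- **Survival.** Exponential event times with per-subtype hazard ratios
  (default (1.0, 1.6, 3.0, 2.2)) on a 0.02 baseline hazard; independent
  exponential censoring whose rate is solved by Brent's method so the
  expected censored fraction equals `censoring_rate` (default 0.3).
- **Mutations.** Three genes with subtype-dependent Bernoulli mutation
  rates, written as minimal MAF rows (missense/nonsense) plus decoy Silent
  rows that downstream filtering must ignore.

One root seed drives deterministic per-assay substreams; identical config
and seed give bit-identical cohort files.

What the generator does *not* emulate: realistic 450k probe densities and
correlation structure, mutation signatures, batch effects, copy-number
breakpoint processes, or confounding between burden and subtype. Passing
recovery tests therefore shows the pipeline identifies the modeled effects
at realistic effect sizes and sample counts — not that it is robust to
every artifact of real tumor data.

## Preprocessing

Probes with more than 30% missing values (the per-probe default;
a 50% variant is exposed for cross-assay matched matrices) or a
sex-chromosome location are removed. Remaining gaps are filled by
k-nearest-neighbor imputation over features (k=10, distance-weighted,
Euclidean over shared samples; delegated to scikit-learn's `KNNImputer`
with features as rows). Segmented copy number maps to genes by
overlap-length-weighted means (1-based inclusive coordinates throughout).
Expression normalization offers quantile normalization on the log2 scale
and log2 fold change against a normal-tissue baseline with pseudocount 1.
Methylation probes map to genes only from CpG-island-associated categories
(Island/Shore/Shelf) in promoter-associated regions (promoter = 2500 bases
upstream of TSS, 5'UTR, first exon).

## Correlation screen

Per gene, Pearson correlations of CNV (and of promoter beta) with log2
expression across samples; p-values from the t distribution on n−2 df;
Fisher z = atanh(r) stabilizes the variance for the skewness summary
(adjusted Fisher–Pearson skewness with the D'Agostino normality test).
Multi-probe genes collapse to one record: the most-negative-r probe for
methylation, the mean r across probes for copy number (both rules
selectable). Gene sets: BH-adjusted correlation p < 0.05 with the sign
constraint (positive for CNVcor, negative for METcor) — the screen's
correlation cutoff is not a fixed |r| but a scale-free FDR rule — followed
by an overall-survival filter (expression tertiles L1/L2/L3, ties at a
boundary assigned to the lower group; log-rank p < 0.05). Whether the OS
filter used expression, CNV or methylation values is not derivable from the
source description; expression is used here since the later prognosis
analyses group by expression tertiles.

## Consensus NMF

Brunet-style NMF minimizes the generalized KL divergence with the classic
multiplicative updates (monotone by construction; asserted in tests).
Signed copy-number matrices are made non-negative by splitting each row
into positive and negative parts (lossless). "50 iterations" in this kind
of analysis refers to random restarts, not update steps: each consensus run
uses 20–50 random restarts (uniform init scaled to the matrix mean,
per-restart substreams), runs updates to a relative objective change of
1e-6 or 2000 iterations, and hard-assigns samples to their argmax metagene.
The consensus matrix (co-clustering frequency) is clustered by
average-linkage hierarchy on 1 − consensus; the cophenetic correlation and
mean silhouette width (both on 1 − consensus) are the rank diagnostics over
k = 2..10 (2..6 in the bundled analysis for runtime). The selected rank
maximizes the cophenetic correlation with silhouette as tie-breaker; among
candidates still tied exactly — which happens only in the saturated regime
where several ranks are perfectly stable — the largest k wins, because a
perfectly reproducible finer split is genuine substructure that a smaller
rank merges. A warning flags searches whose best cophenetic is below 0.9.

## Integrative clustering

The joint model is the Gaussian latent-factor formulation: standardized
data types X_t = W_t Z + eps_t, Z ~ N(0, I_K), diagonal noise Psi_t, and a
lasso penalty on the loadings. EM uses the exact E-step; the M-step solves
the penalized loading problem by coordinate descent (soft-thresholding with
per-feature threshold lambda·psi_j) and updates Psi in closed form, making
the penalized observed log-likelihood non-decreasing (generalized EM;
asserted in tests with 1e-8 relative slack for the psi floor at 1e-8).
Cluster labels are k-means (K+1 centers, seeded, 10 inits) on the
per-sample latent expectations; 20 random restarts are fitted and the best
penalized log-likelihood kept. K is chosen among {2, 3} by restart
stability (mean pairwise adjusted Rand index across restart labelings),
exact ties resolving to the larger K for the same saturation reason as the
NMF rank rule; stabilities below 0.8 for every candidate raise a
structureless-data warning (pure noise measures ~0.6–0.75 because k-means
on a stable noise subspace is fairly repeatable). The default penalty is
lambda = 0.05 on standardized features; `tune_lambda` provides a small
stability grid (0.01/0.05/0.15) when a data-driven choice is wanted. With
lambda = 0 and one data type the model reduces to factor analysis; its
latent subspace matches scikit-learn's `FactorAnalysis` (canonical
correlation > 0.99) but differs slightly from PCA because the noise is
heteroscedastic — the tests check both.

## Survival, states, differential features

Kaplan–Meier uses the product-limit estimator with deaths processed before
censorings at tied times; log-rank tests (any number of groups, chi-square
asymptotics, no continuity correction) delegate to lifelines, with a
permutation oracle kept in the tests. Abnormality states: copy-number
Loss/Normal/Gain at ±0.3 (the 0.2 variant is configuration), methylation
Hypo/Normal/Hyper at absolute beta 0.2/0.8 (a normal-subtracted delta
variant is configuration). Per-sample burdens are abnormal-state fractions;
linkage is pairwise Pearson correlation, and the headline coupling estimate
correlates total CNV burden (gain+loss) with total methylation burden
(hyper+hypo).

Between-subtype comparisons use a two-sided Fisher exact test implemented
by hypergeometric enumeration (p = sum of table probabilities not exceeding
the observed one, with the customary 1+1e-7 relative tie tolerance; scipy's
implementation is the independent oracle in tests). Three-level state
matrices collapse to direction-specific 2×2 tables (abnormal-vs-not per
direction) rather than a 2×3 exact test. Differential expression is a
self-contained negative-binomial Wald procedure — median-of-ratios size
factors, method-of-moments dispersion pooled within groups (floored at
1e-8), Wald test on the log2 fold change of normalized group means with a
0.5 pseudo-mean — deliberately a documented stand-in, not a reimplementation
of any external count-DE package; its null calibration and power are
simulation-tested. Mutation tests use mutated-vs-not Fisher tests at
P < 0.01 after removing synonymous ("Silent") variants and keeping missense
and nonsense classes. The concordant-gene list intersects genes significant
in the methylation, copy-number and expression comparisons, optionally
restricted to the hypermethylated-and-downregulated pattern, ordered by
combined p-value rank.

## Problem sizes and numerical choices

The bundled analysis and the acceptance script run at the cohort scale the
generator defaults to (200 samples, 2000 genes, 100 planted genes per
class) with 20 restarts for consensus NMF and the latent model, rank search
over k = 2..6, and 10–20 seed replicates for the statistical summaries —
sizes chosen so the full analysis reproduces in minutes on a laptop while
keeping every recovery margin wide. Degenerate inputs are contracts, not
surprises: constant vectors are undefined correlations, empty filter
results raise with the threshold named, restarts that empty a cluster are
retried on fresh substreams (at most 5) before being flagged, and constant
burden columns yield flagged NaNs rather than errors.

## Known limitations

- The latent-model cluster count is fixed at K+1; no automatic search above
  the configured candidates.
- The DE stand-in shrinks nothing: no dispersion shrinkage or LFC
  moderation, so it is less powerful than modern count-DE packages at small
  n (its tests use n ≥ 20 per group).
- Burden linkage is gene-level, not segment-level.
- The survival module is deliberately minimal (no Cox regression or
  multivariable adjustment).
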