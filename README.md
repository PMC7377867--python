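# melsubtypes

Integrative subtyping of melanoma-like tumor cohorts from copy number, DNA
methylation and expression — with a synthetic multi-omic cohort generator
that makes every stage of the analysis testable.

## The problem

In cutaneous melanoma, transcriptional dysregulation has two major genomic
drivers: copy-number dosage (more copies, more transcript) and promoter
methylation (more methylation, less transcript). Genes whose expression
tracks their copy number (**CNVcor**) or their promoter beta value
(**METcor**) mark the samples where these mechanisms are active, and
clustering tumors on those gene sets yields subtypes with different
prognoses. This package implements that analysis for anyone who wants to
run it on their own gene-level matrices or study its statistical behavior:

1. **Correlation screen.** Per gene, Pearson r between CNV (or promoter
   beta) and log2 expression across samples; Fisher z = atanh(r) stabilizes
   variance; the z distribution skews right for CNV and left for
   methylation when the mechanisms are real. Gene sets are selected by a
   BH-adjusted sign-constrained rule (q < 0.05, r > 0 for CNVcor / r < 0
   for METcor) plus an overall-survival filter (expression tertiles
   L1/L2/L3, log-rank p < 0.05).
2. **Consensus NMF.** Brunet multiplicative updates minimizing
   D_KL(V ‖ WH) over random restarts; co-clustering frequencies form a
   consensus matrix whose cophenetic correlation and silhouette select the
   rank k ∈ 2..10.
3. **Integrative clustering.** A joint Gaussian latent model
   X_t = W_t Z + ε_t (Z ∈ R^K shared across data types, diagonal Ψ_t,
   lasso-penalized W_t) fitted by EM with soft-thresholding; k-means on
   E[Z|X] gives K+1 subtypes; K chosen by restart stability.
4. **Characterization.** Kaplan–Meier / log-rank survival, per-sample
   abnormality burdens (CNV gain/loss at ±0.3, methylation hypo/hyper at
   beta 0.2/0.8) and their cross-assay linkage, Fisher exact state tests,
   a negative-binomial Wald differential-expression procedure, mutation
   frequency tests (synonymous removed, P < 0.01), and the concordant-gene
   intersection.

Real cohort-scale inputs are not redistributable, so
`melsubtypes.synthetic` generates cohorts with the structure the analysis
assumes — planted CNVcor/METcor genes, latent subtypes, coupled per-sample
abnormality burdens, subtype-dependent hazards and mutation rates — and
returns the ground truth, turning every pipeline stage into a
parameter-recovery experiment. See `docs/methods.md` for the model details.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
generated cohort (200 samples, 2000 genes, 100 planted genes per class):

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_preprocess.py
python analysis/03_correlation_screen.py
python analysis/04_nmf_subtypes.py
python analysis/05_integrative_clustering.py
python analysis/06_survival.py
python analysis/07_burden_linkage.py
python analysis/08_differential_features.py
```

Selected output (seed 0):

```
CNV->expression z: skewness +3.604 (p=6.54e-237); MET->expression z: skewness -3.569 (p=7.17e-235)
CNVcor features: k*=4 (cophenetic 1.000, silhouette 0.995), cluster sizes {'N1': 48, 'N2': 51, 'N3': 48, 'N4': 53}
chosen K=3 -> 4 integrative subtypes, sizes {'iC1': 48, 'iC2': 51, 'iC3': 53, 'iC4': 48}
integrative vs NMF subtype overlap: chi2=584.4, p=4.58e-120
log-rank across 4 subtypes: chi2=21.4, df=3, p=8.82e-05
total CNV burden vs total MET burden: r = 0.642
  differentially mutated genes (p<0.01): 3 -> ['G1999', 'G1998', 'G1997']
```

Reading this: the correlation screen sees the planted mechanisms as a
right-skewed CNV z distribution and left-skewed methylation z distribution;
consensus NMF picks the true rank (4 subtypes) on the CNVcor genes; the
integrative model prefers K=3 (i.e. 4 clusters) and its labels match both
the NMF labels (χ² p ≈ 1e-120) and the planted subtypes; the subtypes
differ in survival (log-rank p ≈ 9e-05); the per-sample CNV and methylation
abnormality burdens are correlated (r = 0.64, against a planted latent
coupling of 0.6); and the three planted subtype-skewed mutation genes are
recovered at P < 0.01.

The same pipeline runs from a single command on any cohort directory in the
documented formats (SEG, TSV matrices, minimal MAF, clinical TSV):

```sh
melsubtypes simulate --out cohort/ --seed 0
melsubtypes all --cohort cohort/ --out results/ --seed 0
```

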