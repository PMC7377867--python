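#!/usr/bin/env python
"""Preprocess the cohort: probe filtering, imputation, segment mapping.

Reads results/cohort/, drops methylation probes with >30% missing values or
a sex-chromosome location, imputes the rest by 10-nearest-neighbor features,
and collapses segmented copy number to gene level. Writes the analysis-ready
matrices to results/02_preprocess/.
"""

import argparse
from pathlib import Path

from melsubtypes import preprocess
from melsubtypes.io import read_cohort, write_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--out", type=Path, default=Path("results/02_preprocess"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

bundle = read_cohort(args.cohort)
n_probes_raw = bundle.met.values.shape[0]
met = preprocess.filter_probes(bundle.met, max_missing_frac=0.30,
                               drop_sex=True, annotation=bundle.annotation)
met = preprocess.knn_impute(met, k=10)
cnv = preprocess.map_segments_to_genes(bundle.segments, bundle.gene_model)

write_matrix(met, args.out / "met_imputed.tsv")
write_matrix(cnv, args.out / "cnv_gene.tsv")

print(f"methylation probes: {n_probes_raw} -> {met.values.shape[0]} "
      "(missingness + sex-chromosome filters), imputed to completeness")
print(f"copy number: {len(bundle.segments)} segments -> "
      f"{cnv.values.notna().any(axis=1).sum()} genes with coverage")
if bundle.mismatches:
    print(f"sample-axis mismatches: {bundle.mismatches}")
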