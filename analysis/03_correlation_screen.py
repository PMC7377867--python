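#!/usr/bin/env python
"""Correlation screen: which genes' expression tracks dosage or methylation?

Correlates gene-level copy number and promoter-probe methylation with log2
expression across samples, Fisher-z-transforms the coefficients, tests the
skew of each distribution, and selects CNVcor / METcor gene sets (BH q<0.05
with the sign constraint, plus a tertile log-rank overall-survival filter at
p<0.05). Writes records, gene sets, chromosome-arm frequencies and CpG/gene
region tallies to results/03_screen/.
"""

import argparse
from pathlib import Path

import pandas as pd

from melsubtypes import preprocess, screen
from melsubtypes.io import read_cohort, read_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--prep", type=Path, default=Path("results/02_preprocess"))
ap.add_argument("--out", type=Path, default=Path("results/03_screen"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

bundle = read_cohort(args.cohort)
met = read_matrix(args.prep / "met_imputed.tsv", "MET")
cnv = read_matrix(args.prep / "cnv_gene.tsv", "CNV")
expr = bundle.expr_log

cnv_rec = screen.correlate_assay_with_expression(cnv, expr)
cnv_rep = screen.select_representative_probe(cnv_rec, rule="mean")
pairing = preprocess.map_probes_to_genes(met, bundle.annotation)
met_rec = screen.correlate_assay_with_expression(met, expr, pairing)
met_rep = screen.select_representative_probe(met_rec, rule="extreme")

skew_c, p_c = screen.skewness_test(cnv_rep["z"])
skew_m, p_m = screen.skewness_test(met_rep["z"])
sets = screen.select_cor_genes(cnv_rep, met_rep, bundle.clinical, expr,
                               q_alpha=0.05, os_alpha=0.05)

cnv_rep.to_csv(args.out / "cnv_records.tsv", sep="\t", index=False)
met_rep.to_csv(args.out / "met_records.tsv", sep="\t", index=False)
for name, genes in [("cnvcor", sets.cnvcor), ("metcor", sets.metcor),
                    ("overlap", sets.overlap)]:
    pd.Series(genes, name="gene").to_csv(args.out / f"{name}_genes.txt",
                                         index=False)
gene_arms = bundle.gene_model.set_index("gene")["arm"]
pd.DataFrame({
    "cnvcor": screen.arm_frequency(sets.cnvcor, gene_arms, gene_arms.index),
    "metcor": screen.arm_frequency(sets.metcor, gene_arms, gene_arms.index),
}).fillna(0.0).to_csv(args.out / "arm_frequency.tsv", sep="\t")
met_probes = met_rep[met_rep["gene"].isin(sets.metcor)]["probe"]
by_cpg, by_region = screen.cpg_category_tally(met_probes, bundle.annotation)
by_cpg.rename("count").to_csv(args.out / "metcor_cpg_tally.tsv", sep="\t")
by_region.rename("count").to_csv(args.out / "metcor_region_tally.tsv", sep="\t")

print(f"CNV->expression z: skewness {skew_c:+.3f} (p={p_c:.2e}); "
      f"MET->expression z: skewness {skew_m:+.3f} (p={p_m:.2e})")
print(f"gene sets after OS filter: CNVcor {len(sets.cnvcor)}, "
      f"METcor {len(sets.metcor)}, overlap {len(sets.overlap)}")
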