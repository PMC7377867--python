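#!/usr/bin/env python
"""Are copy-number and methylation abnormality burdens linked per sample?

Calls gene-level states (Loss/Normal/Gain at +-0.3; Hypo/Normal/Hyper at
0.2/0.8 beta), computes each sample's abnormal-state fractions, and
correlates the four burdens pairwise plus the total CNV burden against the
total methylation burden. Writes tables to results/07_linkage/.
"""

import argparse
from pathlib import Path

import pandas as pd

from melsubtypes import states
from melsubtypes.containers import OmicsMatrix
from melsubtypes.io import read_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--prep", type=Path, default=Path("results/02_preprocess"))
ap.add_argument("--screen", type=Path, default=Path("results/03_screen"))
ap.add_argument("--out", type=Path, default=Path("results/07_linkage"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cnv = read_matrix(args.prep / "cnv_gene.tsv", "CNV")
met = read_matrix(args.prep / "met_imputed.tsv", "MET")
met_rep = pd.read_csv(args.screen / "met_records.tsv", sep="\t")
met_gene = OmicsMatrix(
    met.values.loc[met_rep["probe"]].set_axis(met_rep["gene"], axis=0), "MET")

cnv_states = states.call_cnv_states(cnv)
met_states = states.call_met_states(met_gene)
burden = states.sample_burden(cnv_states, met_states)
r, p = states.burden_linkage(burden)
coupling = states.cross_assay_burden_correlation(burden)

burden.to_csv(args.out / "burden.tsv", sep="\t")
r.to_csv(args.out / "linkage_r.tsv", sep="\t")
p.to_csv(args.out / "linkage_p.tsv", sep="\t")
cnv_states.values.to_csv(args.out / "cnv_states.tsv", sep="\t")
met_states.values.to_csv(args.out / "met_states.tsv", sep="\t")

print("pairwise burden correlations:")
print(r.round(3).to_string())
print(f"total CNV burden vs total MET burden: r = {coupling:.3f}")
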