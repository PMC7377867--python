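#!/usr/bin/env python
"""Survival differences among the integrative subtypes.

Kaplan-Meier curves per subtype, the multi-group log-rank test, and the
identification of the worst- and best-prognosis subtypes (by median KM
time), which the differential-feature comparisons use as the contrast.
Writes curves and test results to results/06_survival/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from melsubtypes import survival
from melsubtypes.io import read_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--labels", type=Path,
                default=Path("results/05_icluster/labels.tsv"))
ap.add_argument("--out", type=Path, default=Path("results/06_survival"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

bundle = read_cohort(args.cohort)
labels = pd.read_csv(args.labels, sep="\t", index_col=0)["icluster_subtype"]
clin = bundle.clinical.set_index("sample").loc[labels.index]

chi2, df, p = survival.log_rank_test(clin["os_time"], clin["os_event"], labels)
curves, medians = [], {}
for level, members in labels.groupby(labels):
    km = survival.km_estimate(clin.loc[members.index, "os_time"],
                              clin.loc[members.index, "os_event"])
    km.insert(0, "group", level)
    curves.append(km)
    below = km[km["survival"] <= 0.5]
    medians[level] = float(below["time"].iloc[0]) if len(below) else np.inf
pd.concat(curves, ignore_index=True).to_csv(args.out / "km_curves.tsv",
                                            sep="\t", index=False)
order = sorted(medians, key=medians.get)
pd.DataFrame({"subtype": order,
              "median_km_time": [medians[k] for k in order]}).to_csv(
    args.out / "median_survival.tsv", sep="\t", index=False)
pd.DataFrame({"chi2": [chi2], "df": [df], "p": [p], "worst": [order[0]],
              "best": [order[-1]]}).to_csv(args.out / "logrank.tsv",
                                           sep="\t", index=False)

print(f"log-rank across {labels.nunique()} subtypes: chi2={chi2:.1f}, "
      f"df={df}, p={p:.2e}")
print("median KM time by subtype:",
      {k: round(v, 1) for k, v in medians.items()})
print(f"worst prognosis: {order[0]}; best: {order[-1]}")
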