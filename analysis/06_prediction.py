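#!/usr/bin/env python
"""Best-subset prediction of rADG from microbiota features.

Builds the per-pig feature matrix (family and genus relative abundances at
both ages plus a rank-filter preselection of OTUs), selects the best linear
model by adjusted R^2, validates it farm-by-farm (leave-one-farm-out refits
of the fixed subset), and compares against the weaning-weight-only baseline.
"""

import argparse
from pathlib import Path

import pandas as pd

from weanotype import abundance, growth, predict
from weanotype.tables import read_count_table, read_metadata, read_taxonomy

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--derived", type=Path, default=Path("results/derived"))
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--p-max", type=int, default=10)
ap.add_argument("--preselect-m", type=int, default=10)
args = ap.parse_args()

filtered = read_count_table(args.derived / "filtered_counts.tsv")
taxonomy = read_taxonomy(args.cohort / "taxonomy.tsv")
meta = read_metadata(args.cohort / "metadata.tsv")

records = growth.classify_within_farm(growth.compute_radg(meta))
rel_otu = abundance.to_relative(filtered)
rel_family = abundance.to_relative(abundance.aggregate(filtered, taxonomy, "family"))
rel_genus = abundance.to_relative(abundance.aggregate(filtered, taxonomy, "genus"))

picked = predict.preselect_otus(rel_otu, meta, records, m=args.preselect_m)
otus = sorted(set(picked["d26"]) | set(picked["d35"]))
print(f"preselected {len(otus)} OTUs by rank-filter class separation")

joined = pd.concat([rel_family.data, rel_genus.data, rel_otu.data[otus]], axis=1)
joined = joined.loc[:, ~joined.columns.duplicated()]
X = predict.build_feature_matrix({"d26": joined, "d35": joined}, meta)
X = X.loc[X.index.intersection(records.index)]
radg = records["radg"]

model = predict.best_subset(X, radg, p_max=args.p_max)
print(f"\nselected model ({model.search} search, "
      f"in-sample adjusted R^2 = {model.adjusted_r2:.3f}):")
print(model.coefficients.round(4).to_string())

per_farm, mean_r2 = predict.leave_one_farm_out(X, radg, records["farm_id"],
                                               model.features)
print(f"\nleave-one-farm-out adjusted R_i^2 (mean {mean_r2:.3f}):")
print(per_farm.round(3).to_string())

baseline = records.loc[X.index, ["weight_d26"]]
base_model = predict.best_subset(baseline, radg, p_max=1)
_, base_mean = predict.leave_one_farm_out(baseline, radg, records["farm_id"],
                                          base_model.features)
print(f"\nweaning-weight-only baseline: cross-validated R^2 = {base_mean:.3f}")

model.coefficients.rename("estimate").rename_axis("variable").to_csv(
    args.derived / "prediction_model.tsv", sep="\t")
per_farm.to_csv(args.derived / "prediction_cv.tsv", sep="\t")
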