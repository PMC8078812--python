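#!/usr/bin/env python
"""Alpha and beta diversity across the weaning transition.

Computes observed richness and Shannon index on the rarefied table, then
tests the age and farm factors on Bray-Curtis distances with PERMANOVA and
the dispersion-homogeneity test.  When farm dispersions are heterogeneous
the farm location test is reported with a caveat rather than suppressed.
"""

import argparse
from pathlib import Path

from weanotype import abundance, diversity
from weanotype.tables import read_count_table, read_metadata

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--derived", type=Path, default=Path("results/derived"))
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--n-perm", type=int, default=999)
args = ap.parse_args()

rarefied = read_count_table(args.derived / "rarefied_counts.tsv")
meta = read_metadata(args.cohort / "metadata.tsv").data.loc[rarefied.data.index]

alpha = diversity.alpha(rarefied)
by_age = alpha.groupby(meta["age_point"]).mean()
print("alpha diversity by age (rarefied):")
print(by_age.round(2).to_string())

rel = abundance.to_relative(rarefied)
dist = diversity.distance(rel, metric="bray_curtis")
for factor in ("age_point", "farm_id"):
    perma = diversity.permanova(dist, meta[factor], args.n_perm, args.seed)
    disp = diversity.dispersion_test(dist, meta[factor], args.n_perm, args.seed)
    caveat = (" [dispersion heterogeneous: interpret location test with caution]"
              if disp["p"] < 0.05 else "")
    print(f"{factor}: PERMANOVA F={perma['F']:.2f} p={perma['p']:.4g}; "
          f"dispersion F={disp['F']:.2f} p={disp['p']:.4g}{caveat}")

out = args.derived / "alpha.tsv"
alpha.join(meta[["age_point", "farm_id"]]).to_csv(out, sep="\t")
dist.to_tsv(args.derived / "bray_curtis.tsv")
print(f"wrote {out} and bray_curtis.tsv")
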